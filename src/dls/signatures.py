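"""Discriminative expression-signature scoring and search.

A signature is a positive gene together with a feature subset on which it
is strongly co-expressed with the other positives and weakly with the
negatives.  Co-expression is the absolute cosine between log-ratio
profiles restricted to the subset, pushed through a logistic soft
threshold so that each strongly co-expressed partner contributes roughly
one "soft neighbour" to the class components; the signature score (ESS)
combines the two components in a bounded ratio with a saturating penalty
on small subsets.  ``signfs`` greedily adds/removes single features to
maximise the score, seeding from the cells with significant expression
change (low FDR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from dls.ontology import TrainingSet
from dls.preprocess import ExpressionDataset

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class SignatureParams:
    """Knobs for signature scoring, search and the bootstrap discard.

    ``beta`` weighs the negative component; ``tau_valid`` is the score a
    signature must exceed to be used downstream; ``fdr_init`` seeds the
    search with the features where the gene changes significantly;
    ``candidate_frac`` bounds additions to the fraction of all features
    with the lowest FDR for the gene.
    """

    beta: float = 1.0
    tau_valid: float = 0.5
    fdr_init: float = 0.1
    candidate_frac: float = 0.2
    sigmoid_midpoint: float = 0.75
    sigmoid_steepness: float = 30.0
    alpha_halfsize: float = 5.0
    max_iters: int = 100
    bootstrap: bool = False
    boot_min_coexpr: float = 0.8
    boot_top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tau_valid < 1):
            raise ValueError("tau_valid must lie in (0, 1)")
        if not (0 < self.candidate_frac <= 1):
            raise ValueError("candidate_frac must lie in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0 <= self.fdr_init <= 1):
            raise ValueError("fdr_init must lie in [0, 1]")
        if self.alpha_halfsize <= 0:
            raise ValueError("alpha_halfsize must be > 0")

    def effective_boot_top_k(self, n_negatives: int) -> int:
        if self.boot_top_k is not None:
            return self.boot_top_k
        return max(1, math.ceil(0.01 * n_negatives))


@dataclass
class ExpressionSignature:
    """A gene, its selected discriminative features, and score components."""

    gene: str
    features: tuple[int, ...]
    ess: float
    c_pos: float
    c_neg: float
    valid: bool
    discarded_negatives: frozenset[str] = frozenset()
    trace: tuple[float, ...] = ()


@dataclass
class SignatureModel:
    """Valid signatures plus the parameters that produced them."""

    signatures: list[ExpressionSignature]
    params: SignatureParams
    training: TrainingSet
    densities: dict | None = None
    prior_pos: float | None = None

    @property
    def valid_signatures(self) -> list[ExpressionSignature]:
        return [s for s in self.signatures if s.valid]


# ---------------------------------------------------------------------------
# scoring primitives


def abs_cosine(x: np.ndarray, y: np.ndarray, features) -> float:
    """|x_F . y_F| / (||x_F|| ||y_F||); 0 when either restriction has zero norm."""
    idx = np.asarray(list(features), dtype=int)
    if idx.size == 0:
        raise ValueError("feature set must be nonempty")
    xf = np.asarray(x, dtype=float)[idx]
    yf = np.asarray(y, dtype=float)[idx]
    nx = np.linalg.norm(xf)
    ny = np.linalg.norm(yf)
    if nx == 0 or ny == 0:
        return 0.0
    return float(min(1.0, abs(np.dot(xf, yf)) / (nx * ny)))


def soft_threshold(c, midpoint: float = 0.75, steepness: float = 30.0):
    """Logistic separation of strong from weak co-expression, in [0, 1]."""
    c = np.asarray(c, dtype=float)
    out = 1.0 / (1.0 + np.exp(-steepness * (c - midpoint)))
    return float(out) if out.ndim == 0 else out


def _abs_cosine_many(x: np.ndarray, rows: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised |cosine| between ``x`` and each row of ``rows`` on ``idx``."""
    xf = x[idx]
    rf = rows[:, idx]
    nx = np.linalg.norm(xf)
    nr = np.linalg.norm(rf, axis=1)
    dots = rf @ xf
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.abs(dots) / (nx * nr)
    cos[~np.isfinite(cos)] = 0.0
    if nx == 0:
        cos[:] = 0.0
    return np.minimum(cos, 1.0)


def _partner_rows(dataset: ExpressionDataset, genes) -> np.ndarray:
    idx = [dataset.gene_index(g) for g in genes]
    return dataset.x_lr[idx] if idx else np.empty((0, dataset.n_features))


def coexpr_components(
    gene: str,
    features,
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams = SignatureParams(),
    discarded: frozenset[str] = frozenset(),
) -> tuple[float, float]:
    """Soft counts of strongly co-expressed positive and negative partners.

    The gene itself is never its own partner; bootstrap-discarded
    negatives are excluded from the negative component.
    """
    idx = np.asarray(sorted(features), dtype=int)
    if idx.size == 0:
        raise ValueError("feature set must be nonempty")
    x = dataset.expression(gene)
    pos_partners = sorted(training.positives - {gene})
    neg_partners = sorted(training.negatives - {gene} - set(discarded))
    if not pos_partners:
        logger.warning("gene %s has no positive partners; c_pos = 0", gene)
        c_pos = 0.0
    else:
        cos = _abs_cosine_many(x, _partner_rows(dataset, pos_partners), idx)
        c_pos = float(
            np.sum(soft_threshold(cos, params.sigmoid_midpoint, params.sigmoid_steepness))
        )
    if not neg_partners:
        c_neg = 0.0
    else:
        cos = _abs_cosine_many(x, _partner_rows(dataset, neg_partners), idx)
        c_neg = float(
            np.sum(soft_threshold(cos, params.sigmoid_midpoint, params.sigmoid_steepness))
        )
    return c_pos, c_neg


def size_penalty(n_features: int, alpha_halfsize: float) -> float:
    """Saturating penalty n/(n+h): small subsets are discounted, large ones -> 1."""
    return n_features / (n_features + alpha_halfsize)


def ess_from_components(
    c_pos: float, c_neg: float, n_features: int, params: SignatureParams
) -> float:
    if n_features == 0:
        return 0.0
    alpha = size_penalty(n_features, params.alpha_halfsize)
    return alpha * c_pos / (c_pos + params.beta * c_neg + _EPS)


def ess(
    gene: str,
    features,
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams = SignatureParams(),
    discarded: frozenset[str] = frozenset(),
) -> float:
    """Expression Signature Score in [0, 1]."""
    c_pos, c_neg = coexpr_components(gene, features, dataset, training, params, discarded)
    return ess_from_components(c_pos, c_neg, len(set(features)), params)


# ---------------------------------------------------------------------------
# bootstrap discard


def bootstrap_discard(
    gene: str,
    features,
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams,
) -> frozenset[str]:
    """Negatives to ignore this iteration: co-expression >= floor AND top-k ranked.

    Ranking is by |cosine| with the gene on the current features,
    descending, ties broken by gene id.
    """
    idx = np.asarray(sorted(features), dtype=int)
    if idx.size == 0:
        return frozenset()
    negs = sorted(training.negatives - {gene})
    if not negs:
        return frozenset()
    cos = _abs_cosine_many(dataset.expression(gene), _partner_rows(dataset, negs), idx)
    order = sorted(range(len(negs)), key=lambda i: (-cos[i], negs[i]))
    top_k = params.effective_boot_top_k(len(negs))
    return frozenset(
        negs[i] for i in order[:top_k] if cos[i] >= params.boot_min_coexpr
    )


# ---------------------------------------------------------------------------
# signFS search


def _candidate_pool(dataset: ExpressionDataset, gene: str, params: SignatureParams) -> list[int]:
    """Features ever eligible for addition: the lowest-FDR fraction for this gene."""
    m = dataset.n_features
    n_pool = max(1, math.ceil(params.candidate_frac * m))
    fdr = dataset.fdr(gene)
    order = sorted(range(m), key=lambda f: (fdr[f], f))
    return order[:n_pool]


def signfs(
    gene: str,
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams = SignatureParams(),
) -> ExpressionSignature:
    """Greedy best-improvement feature-subset search for one gene.

    Seeds with the features where the gene's change is significant
    (FDR < ``fdr_init``); at each iteration applies the single-feature
    addition (restricted to the low-FDR candidate pool) or removal that
    most increases the score, ties broken by lowest feature index, and
    stops when no move strictly improves or ``max_iters`` is reached.
    An empty seed yields an empty invalid signature.
    """
    fdr = dataset.fdr(gene)
    current = {f for f in range(dataset.n_features) if fdr[f] < params.fdr_init}
    if not current:
        logger.warning("gene %s: no significant features to seed signFS", gene)
        return ExpressionSignature(
            gene=gene, features=(), ess=0.0, c_pos=0.0, c_neg=0.0, valid=False
        )
    pool = set(_candidate_pool(dataset, gene, params))

    def score(feats: set[int], discarded: frozenset[str]) -> tuple[float, float, float]:
        if not feats:
            return 0.0, 0.0, 0.0
        c_pos, c_neg = coexpr_components(gene, feats, dataset, training, params, discarded)
        return ess_from_components(c_pos, c_neg, len(feats), params), c_pos, c_neg

    discarded: frozenset[str] = frozenset()
    if params.bootstrap:
        discarded = bootstrap_discard(gene, current, dataset, training, params)
    cur_ess, cur_cp, cur_cn = score(current, discarded)
    trace = [cur_ess]

    for _ in range(params.max_iters):
        if params.bootstrap:
            discarded = bootstrap_discard(gene, current, dataset, training, params)
            cur_ess, cur_cp, cur_cn = score(current, discarded)
        best: tuple[float, int, str] | None = None  # (ess, feature, kind)

        def consider(cand_ess: float, f: int, kind: str) -> None:
            nonlocal best
            if cand_ess <= cur_ess:
                return
            if best is None or cand_ess > best[0] or (cand_ess == best[0] and f < best[1]):
                best = (cand_ess, f, kind)

        for f in sorted(pool - current):
            consider(score(current | {f}, discarded)[0], f, "add")
        for f in sorted(current):
            consider(score(current - {f}, discarded)[0], f, "remove")
        if best is None:
            break
        _, f, kind = best
        if kind == "add":
            current.add(f)
        else:
            current.remove(f)
        prev_ess = cur_ess
        cur_ess, cur_cp, cur_cn = score(current, discarded)
        # strict improvement is guaranteed under the discard set the move was
        # chosen with; across iterations the bootstrap may rebase the score
        assert cur_ess > prev_ess, "signFS move must strictly improve the score"
        trace.append(cur_ess)

    return ExpressionSignature(
        gene=gene,
        features=tuple(sorted(current)),
        ess=cur_ess,
        c_pos=cur_cp,
        c_neg=cur_cn,
        valid=cur_ess > params.tau_valid and bool(current),
        discarded_negatives=discarded,
        trace=tuple(trace),
    )


def train(
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams = SignatureParams(),
) -> SignatureModel:
    """One independent signFS run per positive gene.

    Only signatures whose score exceeds ``tau_valid`` are marked valid and
    used downstream; a model with zero valid signatures is returned with a
    warning.
    """
    training = training.restricted_to(dataset.gene_ids)
    signatures = [signfs(g, dataset, training, params) for g in sorted(training.positives)]
    model = SignatureModel(signatures=signatures, params=params, training=training)
    if not model.valid_signatures:
        logger.warning("training produced zero valid signatures")
    return model
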