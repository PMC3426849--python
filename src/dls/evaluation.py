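"""Evaluation harness: cross-validation, enrichment, and the CN baseline.

Implements stratified k-fold cross-validation with precision / recall /
precision-weighted F-beta, upper-tail hypergeometric enrichment of
predictions against a later annotation release, and a guilt-by-association
co-expression-network baseline with Bonferroni-corrected hypergeometric
neighbourhood tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from dls.classify import fit_densities, predict_genes
from dls.evaluation_metrics import precision_recall_fbeta
from dls.fnd import run_fnd
from dls.ontology import TrainingSet
from dls.preprocess import ExpressionDataset
from dls.signatures import SignatureParams, train

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "EnrichmentResult",
    "MethodConfig",
    "precision_recall_fbeta",
    "cross_validate",
    "hypergeom_enrichment",
    "cn_baseline_predict",
    "usefulness_summary",
]


@dataclass
class EvalReport:
    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f_beta: float
    folds: int
    repeats: int
    seed: int


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    pred_set_size: int
    new_annot_size: int
    universe_size: int
    p_value: float


@dataclass(frozen=True)
class MethodConfig:
    """Which method cross-validation runs and with what knobs."""

    method: str = "dls"  # dls | fnd-dls | cn
    signature_params: SignatureParams = field(default_factory=SignatureParams)
    conf_threshold: float = 0.9
    bandwidth_spec: float | str = "silverman"
    beta: float = 2.0
    cn_corr_threshold: float = 0.6
    cn_p_threshold: float = 0.1
    fnd_max_iter: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("dls", "fnd-dls", "cn"):
            raise ValueError(f"unknown method {self.method!r}")


def hypergeom_enrichment(
    pred_genes: set[str],
    new_annot_genes: set[str],
    universe: set[str],
    term: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= overlap)."""
    if not universe:
        raise ValueError("universe is empty")
    pred = set(pred_genes) & universe
    annot = set(new_annot_genes) & universe
    overlap = len(pred & annot)
    # sf(k-1) = P(X >= k) with population |U|, successes |annot|, draws |pred|
    p = float(hypergeom.sf(overlap - 1, len(universe), len(annot), len(pred)))
    return EnrichmentResult(
        term=term,
        overlap=overlap,
        pred_set_size=len(pred),
        new_annot_size=len(annot),
        universe_size=len(universe),
        p_value=min(1.0, max(0.0, p)),
    )


def cn_baseline_predict(
    dataset: ExpressionDataset,
    training: TrainingSet,
    corr_threshold: float = 0.6,
    p_threshold: float = 0.1,
) -> set[str]:
    """Guilt-by-association over a global co-expression network.

    Genes are linked when their |cosine| over *all* features reaches
    ``corr_threshold``; each gene with neighbours is tested for
    hypergeometric enrichment of positives among its neighbours, with
    Bonferroni correction over the number of tested genes.
    """
    if not (0 < corr_threshold <= 1) or not (0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1]")
    genes = dataset.gene_ids
    n = len(genes)
    positives = training.positives

    norms = np.linalg.norm(dataset.x_lr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = dataset.x_lr / norms[:, None]
    unit[~np.isfinite(unit)] = 0.0
    cos = np.abs(unit @ unit.T)
    np.fill_diagonal(cos, 0.0)

    raw: dict[str, float] = {}
    for i, g in enumerate(genes):
        nbr_idx = np.nonzero(cos[i] >= corr_threshold)[0]
        if nbr_idx.size == 0:
            continue
        nbrs = {genes[j] for j in nbr_idx}
        k = len(nbrs & positives)
        universe = n - 1  # all other genes
        succ = len(positives - {g})
        raw[g] = float(hypergeom.sf(k - 1, universe, succ, len(nbrs)))
    if not raw:
        return set()
    bonf = len(raw)
    return {g for g, p in raw.items() if min(1.0, p * bonf) <= p_threshold}


def _stratified_folds(
    genes: list[str], k: int, rng: np.random.Generator
) -> list[list[str]]:
    order = list(rng.permutation(sorted(genes)))
    return [order[i::k] for i in range(k)]


def _predict_fold(
    dataset: ExpressionDataset,
    fold_training: TrainingSet,
    test_genes: list[str],
    config: MethodConfig,
) -> set[str]:
    if config.method == "cn":
        return cn_baseline_predict(
            dataset, fold_training, config.cn_corr_threshold, config.cn_p_threshold
        ) & set(test_genes)
    training = fold_training
    if config.method == "fnd-dls":
        _, training = run_fnd(
            dataset,
            fold_training,
            config.signature_params,
            max_iter=config.fnd_max_iter,
            conf_threshold=config.conf_threshold,
            bandwidth_spec=config.bandwidth_spec,
        )
    model = train(dataset, training, config.signature_params)
    if not model.valid_signatures:
        return set()
    fit_densities(model, dataset, training, config.bandwidth_spec)
    preds = predict_genes(model, dataset, test_genes, config.conf_threshold)
    return {p.gene for p in preds}


def cross_validate(
    dataset: ExpressionDataset,
    training: TrainingSet,
    config: MethodConfig = MethodConfig(),
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation, repeated with fresh partitions.

    Positives and negatives are split into k folds separately; per fold
    the model trains on the remaining genes and is scored on the held-out
    ones.  Counts accumulate over folds within a repeat; metrics are
    averaged over repeats.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    training = training.restricted_to(dataset.gene_ids)
    if len(training.positives) < k or len(training.negatives) < k:
        raise ValueError(
            f"both classes need >= k={k} members "
            f"(have {len(training.positives)} positives, {len(training.negatives)} negatives); "
            "use a smaller k"
        )
    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        pos_folds = _stratified_folds(sorted(training.positives), k, rng)
        neg_folds = _stratified_folds(sorted(training.negatives), k, rng)
        tp = fp = fn = 0
        for fold in range(k):
            te_pos = pos_folds[fold]
            te_neg = neg_folds[fold]
            tr_pos = {g for f in range(k) if f != fold for g in pos_folds[f]}
            tr_neg = {g for f in range(k) if f != fold for g in neg_folds[f]}
            fold_training = TrainingSet(
                process_term=training.process_term,
                positives=tr_pos,
                negatives=tr_neg,
                negative_terms=set(training.negative_terms),
            )
            predicted = _predict_fold(dataset, fold_training, te_pos + te_neg, config)
            tp += len(predicted & set(te_pos))
            fp += len(predicted & set(te_neg))
            fn += len(set(te_pos) - predicted)
        p, r, f = precision_recall_fbeta(tp, fp, fn, beta=config.beta)
        per_repeat.append((tp, fp, fn, p, r, f))
    arr = np.asarray(per_repeat, dtype=float)
    means = arr.mean(axis=0)
    return EvalReport(
        tp=float(means[0]), fp=float(means[1]), fn=float(means[2]),
        precision=float(means[3]), recall=float(means[4]), f_beta=float(means[5]),
        folds=k, repeats=repeats, seed=seed,
    )


def usefulness_summary(
    reports: dict[str, list[EvalReport]], precision_floor: float = 1 / 3
) -> dict:
    """Per-method useful-run counts plus a pairwise-wins matrix by F-beta.

    A run is *useful* when its precision exceeds the floor.  Wins between
    methods A and B are counted over runs where at least one of the two
    is useful (mirroring the rule of only comparing useful predictions).
    """
    if not (0 < precision_floor < 1):
        raise ValueError("precision_floor must lie in (0, 1)")
    useful_counts = {
        m: sum(1 for r in rs if r.precision > precision_floor) for m, rs in reports.items()
    }
    methods = sorted(reports)
    wins: dict[tuple[str, str], int] = {}
    for a in methods:
        for b in methods:
            if a == b:
                continue
            count = 0
            for ra, rb in zip(reports[a], reports[b]):
                if max(ra.precision, rb.precision) <= precision_floor:
                    continue
                if ra.f_beta > rb.f_beta:
                    count += 1
            wins[(a, b)] = count
    return {"useful_counts": useful_counts, "pairwise_wins": wins}
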