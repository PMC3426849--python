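"""Kernel-density Bayes classification of co-expression levels.

Each valid signature gets two class-conditional Gaussian KDEs — the
co-expression levels of the training positives and negatives against the
signature — plus the class prior.  A gene's co-expression ``L`` with a
signature then maps to a posterior probability of class membership, so a
fixed confidence threshold translates into a different minimum
co-expression per signature (adaptive thresholding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from dls.ontology import TrainingSet
from dls.preprocess import ExpressionDataset
from dls.signatures import (
    ExpressionSignature,
    SignatureModel,
    _abs_cosine_many,
    _partner_rows,
)
from dls.evaluation_metrics import precision_recall_fbeta

logger = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-12
MIN_BANDWIDTH = 0.01
CV_BANDWIDTH_GRID = (0.01, 0.02, 0.05, 0.1, 0.2)


@dataclass
class SignatureDensityModel:
    """Class-conditional co-expression samples and KDE bandwidths for a signature.

    ``bandwidth`` is either one shared sigma or a (positive, negative)
    pair — the two class-conditional densities may be smoothed
    differently (Silverman's rule is applied per sample set).
    """

    signature: ExpressionSignature
    pos_samples: np.ndarray
    neg_samples: np.ndarray
    bandwidth: float | tuple[float, float]
    prior_pos: float

    def __post_init__(self) -> None:
        self.pos_samples = np.asarray(self.pos_samples, dtype=float)
        self.neg_samples = np.asarray(self.neg_samples, dtype=float)
        if isinstance(self.bandwidth, tuple):
            self.bandwidth_pos, self.bandwidth_neg = self.bandwidth
        else:
            self.bandwidth_pos = self.bandwidth_neg = self.bandwidth
        if self.bandwidth_pos <= 0 or self.bandwidth_neg <= 0:
            raise ValueError("bandwidth must be > 0")
        if not (0 < self.prior_pos < 1):
            raise ValueError("prior_pos must lie in (0, 1)")


@dataclass(frozen=True)
class Prediction:
    gene: str
    signature_gene: str
    coexpression: float
    confidence: float


def kde_density(samples: np.ndarray, bandwidth: float, x):
    """Gaussian-kernel density estimate, floored at ``DENSITY_FLOOR``."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError(
            "need at least 2 samples for a density estimate; "
            "merge classes or fall back to a fixed bandwidth"
        )
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    z = (x_arr[:, None] - samples[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (samples.size * bandwidth * np.sqrt(2 * np.pi))
    dens = np.maximum(dens, DENSITY_FLOOR)
    return float(dens[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else dens


def posterior(L, density_model: SignatureDensityModel):
    """P(positive | co-expression L) by Bayes rule with class-conditional KDEs."""
    pi = density_model.prior_pos
    f_pos = kde_density(density_model.pos_samples, density_model.bandwidth_pos, L)
    f_neg = kde_density(density_model.neg_samples, density_model.bandwidth_neg, L)
    return pi * f_pos / (pi * f_pos + (1 - pi) * f_neg)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """1.06 * sd * n^(-1/5), floored at ``MIN_BANDWIDTH`` for degenerate samples."""
    samples = np.asarray(samples, dtype=float)
    sd = samples.std(ddof=1) if samples.size > 1 else 0.0
    bw = 1.06 * sd * samples.size ** (-0.2)
    if not np.isfinite(bw) or bw < MIN_BANDWIDTH:
        logger.debug("Silverman bandwidth %g below floor; using %g", bw, MIN_BANDWIDTH)
        return MIN_BANDWIDTH
    return float(bw)


def _coexpression_samples(
    sig: ExpressionSignature, dataset: ExpressionDataset, genes: list[str]
) -> np.ndarray:
    idx = np.asarray(sig.features, dtype=int)
    partners = [g for g in genes if g != sig.gene]
    if not partners:
        return np.empty(0)
    return _abs_cosine_many(dataset.expression(sig.gene), _partner_rows(dataset, partners), idx)


def _build_density(
    sig: ExpressionSignature,
    dataset: ExpressionDataset,
    positives: list[str],
    negatives: list[str],
    bandwidth: float | None,
    prior: float,
) -> SignatureDensityModel:
    pos = _coexpression_samples(sig, dataset, positives)
    neg = _coexpression_samples(sig, dataset, negatives)
    if bandwidth is None:
        bw: float | tuple[float, float] = (
            silverman_bandwidth(pos),
            silverman_bandwidth(neg),
        )
    else:
        bw = bandwidth
    return SignatureDensityModel(
        signature=sig, pos_samples=pos, neg_samples=neg, bandwidth=bw, prior_pos=prior
    )


def fit_densities(
    model: SignatureModel,
    dataset: ExpressionDataset,
    training: TrainingSet | None = None,
    bandwidth_spec: float | str = "silverman",
) -> SignatureModel:
    """Attach a :class:`SignatureDensityModel` to every valid signature.

    ``bandwidth_spec`` is a fixed float, ``"silverman"`` (rule-of-thumb per
    sample set, shared max of the two classes), or ``"cv"`` (grid search
    over ``CV_BANDWIDTH_GRID`` by 3-fold cross-validated F2 on the
    training genes).
    """
    training = training or model.training
    if not model.valid_signatures:
        raise ValueError("model has no valid signatures")
    positives = sorted(training.positives)
    negatives = sorted(training.negatives)
    prior = len(positives) / (len(positives) + len(negatives))

    if bandwidth_spec == "cv":
        bw = _cv_bandwidth(model, dataset, positives, negatives, prior)
        bandwidth: float | None = bw
    elif bandwidth_spec == "silverman":
        bandwidth = None
    else:
        bandwidth = float(bandwidth_spec)

    model.densities = {
        sig.gene: _build_density(sig, dataset, positives, negatives, bandwidth, prior)
        for sig in model.valid_signatures
    }
    model.prior_pos = prior
    return model


def _cv_bandwidth(
    model: SignatureModel,
    dataset: ExpressionDataset,
    positives: list[str],
    negatives: list[str],
    prior: float,
    k: int = 3,
    conf_threshold: float = 0.5,
    beta: float = 2.0,
    seed: int = 0,
) -> float:
    """Pick the grid bandwidth with the best held-out F-beta on training genes."""
    rng = np.random.default_rng(seed)
    pos_folds = _fold_assignment(len(positives), k, rng)
    neg_folds = _fold_assignment(len(negatives), k, rng)
    best_bw, best_f = CV_BANDWIDTH_GRID[0], -1.0
    for bw in CV_BANDWIDTH_GRID:
        tp = fp = fn = 0
        for fold in range(k):
            tr_pos = [g for g, f in zip(positives, pos_folds) if f != fold]
            tr_neg = [g for g, f in zip(negatives, neg_folds) if f != fold]
            te_pos = [g for g, f in zip(positives, pos_folds) if f == fold]
            te_neg = [g for g, f in zip(negatives, neg_folds) if f == fold]
            dens = {}
            for sig in model.valid_signatures:
                pos_s = _coexpression_samples(sig, dataset, tr_pos)
                neg_s = _coexpression_samples(sig, dataset, tr_neg)
                if pos_s.size < 2 or neg_s.size < 2:
                    continue
                dens[sig.gene] = SignatureDensityModel(
                    signature=sig, pos_samples=pos_s, neg_samples=neg_s,
                    bandwidth=bw, prior_pos=prior,
                )
            if not dens:
                continue
            predicted = _predict_geneset(dens, dataset, te_pos + te_neg, conf_threshold)
            tp += len(predicted & set(te_pos))
            fp += len(predicted & set(te_neg))
            fn += len(set(te_pos) - predicted)
        _, _, f = precision_recall_fbeta(tp, fp, fn, beta=beta)
        if f > best_f:
            best_f, best_bw = f, bw
    return best_bw


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.arange(n) % k
    return rng.permutation(folds)


def _predict_geneset(
    densities: dict[str, SignatureDensityModel],
    dataset: ExpressionDataset,
    genes: list[str],
    conf_threshold: float,
) -> set[str]:
    out: set[str] = set()
    for dm in densities.values():
        sig = dm.signature
        idx = np.asarray(sig.features, dtype=int)
        targets = [g for g in genes if g != sig.gene]
        if not targets:
            continue
        cos = _abs_cosine_many(dataset.expression(sig.gene), _partner_rows(dataset, targets), idx)
        conf = posterior(cos, dm)
        out.update(g for g, c in zip(targets, conf) if c > conf_threshold)
    return out


def predict_genes(
    model: SignatureModel,
    dataset: ExpressionDataset,
    genes: list[str],
    conf_threshold: float = 0.9,
) -> list[Prediction]:
    """Predictions of the given genes against every valid signature.

    Emits one :class:`Prediction` per (signature, gene) pair whose
    posterior exceeds the confidence threshold; the signature's own gene
    is never a target of itself.
    """
    if model.densities is None:
        raise ValueError("fit_densities must be called before prediction")
    if not model.valid_signatures:
        logger.warning("no valid signatures; returning no predictions")
        return []
    preds: list[Prediction] = []
    for sig in model.valid_signatures:
        dm = model.densities[sig.gene]
        idx = np.asarray(sig.features, dtype=int)
        targets = [g for g in genes if g != sig.gene]
        if not targets:
            continue
        cos = _abs_cosine_many(dataset.expression(sig.gene), _partner_rows(dataset, targets), idx)
        conf = posterior(cos, dm)
        for g, L, c in zip(targets, cos, conf):
            if c > conf_threshold:
                preds.append(Prediction(gene=g, signature_gene=sig.gene,
                                        coexpression=float(L), confidence=float(c)))
    preds.sort(key=lambda p: (p.signature_gene, p.gene))
    return preds


def predict_all(
    model: SignatureModel,
    dataset: ExpressionDataset,
    conf_threshold: float = 0.9,
) -> list[Prediction]:
    """Genome-wide prediction: every gene (training genes included) vs every signature."""
    return predict_genes(model, dataset, list(dataset.gene_ids), conf_threshold)
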