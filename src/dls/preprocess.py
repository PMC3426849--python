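"""Pre-processing of replicated raw expression intensities.

Turns intensity tables grouped into control--test condition pairs into two
parallel genes x features matrices: ``X_LR`` (log2 fold changes) and
``X_FDR`` (per-cell false discovery rates from a rank-product permutation
test).  Condition pairs can be supplied manually or enumerated
automatically with a greedy redundancy filter.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: exhaustive label enumeration is used when the number of distinct
#: control/test assignments does not exceed this bound.
EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class ConditionPair:
    """One control--test comparison inside an experiment."""

    experiment_id: str
    control: str
    test: str

    def __post_init__(self) -> None:
        if self.control == self.test:
            raise ValueError(
                f"control and test conditions must differ (got {self.control!r})"
            )

    @property
    def feature_id(self) -> str:
        return f"{self.experiment_id}:{self.control}_vs_{self.test}"


@dataclass
class RawExperimentSet:
    """A replicated multi-condition experiment.

    Parameters
    ----------
    experiment_id:
        Opaque identifier.
    gene_ids:
        Ordered unique gene identifiers (rows of ``intensities``).
    sample_ids:
        Ordered sample identifiers (columns of ``intensities``).
    intensities:
        Non-negative genes x samples matrix.
    sample_condition:
        Maps every sample id to one condition label.
    """

    experiment_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    sample_condition: dict[str, str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, s = self.intensities.shape
        if n != len(self.gene_ids):
            raise ValueError("row count does not match gene_ids")
        if s != len(self.sample_ids):
            raise ValueError("column count does not match sample_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        missing = [s_ for s_ in self.sample_ids if s_ not in self.sample_condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.sample_condition[s], None)
        return list(seen)

    def condition_columns(self, condition: str) -> list[int]:
        cols = [
            j for j, s in enumerate(self.sample_ids) if self.sample_condition[s] == condition
        ]
        if not cols:
            raise KeyError(
                f"condition {condition!r} not present in experiment {self.experiment_id!r}"
            )
        return cols

    def condition_matrix(self, condition: str) -> np.ndarray:
        return self.intensities[:, self.condition_columns(condition)]


@dataclass
class ExpressionDataset:
    """Paired log-ratio and FDR matrices over genes x features."""

    gene_ids: list[str]
    features: list[ConditionPair]
    x_lr: np.ndarray
    x_fdr: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.x_lr = np.asarray(self.x_lr, dtype=float)
        self.x_fdr = np.asarray(self.x_fdr, dtype=float)
        if self.x_lr.shape != self.x_fdr.shape:
            raise ValueError("X_LR and X_FDR must have identical shape")
        if self.x_lr.shape != (len(self.gene_ids), len(self.features)):
            raise ValueError("matrix shape does not match gene/feature lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            raise ValueError("feature ids must be unique")
        if self.x_fdr.size and (self.x_fdr.min() < 0 or self.x_fdr.max() > 1):
            raise ValueError("X_FDR entries must lie in [0, 1]")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def expression(self, gene: str) -> np.ndarray:
        return self.x_lr[self.gene_index(gene)]

    def fdr(self, gene: str) -> np.ndarray:
        return self.x_fdr[self.gene_index(gene)]


# ---------------------------------------------------------------------------
# rank products


def _rank_product_stats(control: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean fold-change ranks over every control/test replicate pairing.

    Rank 1 marks the most up-regulated gene in the up statistic and the most
    down-regulated in the down statistic.  Ties receive average ranks.
    """
    n_genes = control.shape[0]
    log_up = np.zeros(n_genes)
    log_down = np.zeros(n_genes)
    n_pairings = 0
    for i in range(control.shape[1]):
        for j in range(test.shape[1]):
            fc = test[:, j] / control[:, i]
            r_up = rankdata(-fc, method="average")
            r_down = rankdata(fc, method="average")
            log_up += np.log(r_up)
            log_down += np.log(r_down)
            n_pairings += 1
    return np.exp(log_up / n_pairings), np.exp(log_down / n_pairings)


def _null_assignments(
    n_control: int, n_test: int, n_perm: int, rng: np.random.Generator
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Control/test column assignments of the pooled samples for the null."""
    n = n_control + n_test
    total = math.comb(n, n_control)
    if total <= EXHAUSTIVE_LIMIT:
        out = []
        all_idx = set(range(n))
        for ctrl in itertools.combinations(range(n), n_control):
            tst = tuple(sorted(all_idx - set(ctrl)))
            out.append((ctrl, tst))
        return out
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        out.append((tuple(perm[:n_control]), tuple(perm[n_control:])))
    return out


def _empirical_fdr(rp_obs: np.ndarray, rp_null: np.ndarray, n_datasets: int) -> np.ndarray:
    """Breitling-style FDR: expected null hits at each observed value over its rank."""
    order = np.sort(rp_null)
    exp_hits = np.searchsorted(order, rp_obs, side="right") / n_datasets
    rank_obs = np.array([np.sum(rp_obs <= v) for v in rp_obs], dtype=float)
    return np.clip(exp_hits / rank_obs, 0.0, 1.0)


def rank_products(
    control: np.ndarray,
    test: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log2 fold change and rank-product FDR for one condition pair.

    Up- and down-regulation are tested separately against a permutation
    null of label-shuffled datasets and merged per gene by the sign of its
    log ratio.  When the number of distinct label assignments is at most
    ``EXHAUSTIVE_LIMIT`` the null is enumerated exhaustively (exact test);
    otherwise ``n_perm`` random assignments are drawn from ``seed``.

    Parameters
    ----------
    control, test:
        Genes x replicates intensity matrices sharing the same gene rows.
    n_perm:
        Random permutations when exhaustive enumeration is infeasible.
    seed:
        Seeds the permutation draw.

    Returns
    -------
    (log_ratio, fdr):
        Both per-gene vectors; ``fdr`` clamped to [0, 1].
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if control.ndim != 2 or test.ndim != 2:
        raise ValueError("control and test must be 2-D (genes x replicates)")
    if control.shape[0] != test.shape[0]:
        raise ValueError(
            f"control has {control.shape[0]} gene rows but test has {test.shape[0]}"
        )
    if control.shape[1] < 1 or test.shape[1] < 1:
        raise ValueError("need at least one replicate per condition")
    if np.any(control <= 0) or np.any(test <= 0):
        raise ValueError("intensities must be > 0; offset non-positive values upstream")

    log_ratio = np.log2(test.mean(axis=1) / control.mean(axis=1))

    rp_up, rp_down = _rank_product_stats(control, test)

    pooled = np.hstack([control, test])
    rng = np.random.default_rng(seed)
    assignments = _null_assignments(control.shape[1], test.shape[1], n_perm, rng)
    null_up = []
    null_down = []
    for ctrl_idx, test_idx in assignments:
        nu, nd = _rank_product_stats(pooled[:, ctrl_idx], pooled[:, test_idx])
        null_up.append(nu)
        null_down.append(nd)
    n_datasets = len(assignments)
    fdr_up = _empirical_fdr(rp_up, np.concatenate(null_up), n_datasets)
    fdr_down = _empirical_fdr(rp_down, np.concatenate(null_down), n_datasets)

    fdr = np.where(log_ratio >= 0, fdr_up, fdr_down)
    return log_ratio, fdr


# ---------------------------------------------------------------------------
# automatic pair generation


def _offset_if_needed(exp: RawExperimentSet) -> np.ndarray:
    """Return intensities with zeros lifted by the smallest positive value."""
    x = exp.intensities
    if np.any(x <= 0):
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError(
                f"experiment {exp.experiment_id!r} has no positive intensities"
            )
        offset = pos.min()
        logger.warning(
            "experiment %s: offsetting non-positive intensities by %g",
            exp.experiment_id,
            offset,
        )
        x = x + offset
    return x


def _pair_log_ratio(exp: RawExperimentSet, control: str, test: str) -> np.ndarray:
    x = _offset_if_needed(exp)
    c = x[:, exp.condition_columns(control)].mean(axis=1)
    t = x[:, exp.condition_columns(test)].mean(axis=1)
    return np.log2(t / c)


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def generate_pairs_auto(
    experiments: list[RawExperimentSet], max_redundancy: float = 0.9
) -> list[ConditionPair]:
    """Enumerate all condition pairs per experiment with a redundancy filter.

    Candidates are visited in deterministic order (sorted condition-label
    pairs, lexicographically smaller label as control) and a candidate is
    kept only if its log-ratio profile has absolute Pearson correlation at
    most ``max_redundancy`` with every already-kept feature of the same
    experiment.
    """
    if not (0 < max_redundancy <= 1):
        raise ValueError("max_redundancy must lie in (0, 1]")
    kept: list[ConditionPair] = []
    for exp in experiments:
        conds = sorted(exp.conditions)
        if len(conds) < 2:
            logger.warning(
                "experiment %s has fewer than 2 conditions; skipped", exp.experiment_id
            )
            continue
        kept_profiles: list[np.ndarray] = []
        for control, test in itertools.combinations(conds, 2):
            lr = _pair_log_ratio(exp, control, test)
            if all(_abs_pearson(lr, p) <= max_redundancy for p in kept_profiles):
                kept.append(ConditionPair(exp.experiment_id, control, test))
                kept_profiles.append(lr)
    return kept


def assemble_dataset(
    experiments: list[RawExperimentSet],
    pairs: list[ConditionPair],
    n_perm: int = 100,
    seed: int = 0,
) -> ExpressionDataset:
    """Run rank products for every condition pair and stack the columns.

    The gene universe is the intersection of the experiments' gene sets
    (in the order of the first experiment); a shrinking intersection is
    logged, an empty pair list is an error.
    """
    if not pairs:
        raise ValueError("pair list is empty")
    by_id = {e.experiment_id: e for e in experiments}
    for p in pairs:
        if p.experiment_id not in by_id:
            raise KeyError(f"pair references unknown experiment {p.experiment_id!r}")

    used = {p.experiment_id for p in pairs}
    universe = None
    for e in experiments:
        if e.experiment_id not in used:
            continue
        genes = set(e.gene_ids)
        universe = genes if universe is None else universe & genes
    first = next(e for e in experiments if e.experiment_id in used)
    gene_ids = [g for g in first.gene_ids if g in universe]
    if len(gene_ids) < len(first.gene_ids):
        logger.warning(
            "gene universe reduced to the %d-gene intersection", len(gene_ids)
        )

    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    lr_cols = []
    fdr_cols = []
    for p, ss in zip(pairs, seeds):
        exp = by_id[p.experiment_id]
        row_idx = [exp.gene_ids.index(g) for g in gene_ids]
        x = _offset_if_needed(exp)[row_idx]
        ctrl = x[:, [c for c in exp.condition_columns(p.control)]]
        tst = x[:, [c for c in exp.condition_columns(p.test)]]
        lr, fdr = rank_products(ctrl, tst, n_perm=n_perm, seed=int(ss.generate_state(1)[0]))
        lr_cols.append(lr)
        fdr_cols.append(fdr)
    return ExpressionDataset(
        gene_ids=gene_ids,
        features=list(pairs),
        x_lr=np.column_stack(lr_cols),
        x_fdr=np.column_stack(fdr_cols),
    )
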