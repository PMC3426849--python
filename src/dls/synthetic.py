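"""Synthetic data with planted ground truth.

Generates log-ratio expression matrices with planted discriminative local
patterns (group templates on feature subsets), a matching FDR matrix with
a controllable mislabelling rate, training labels with optional planted
false negatives, and small random ontologies with annotations — so the
whole pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dls.ontology import AnnotationSet, OntologyDAG, TrainingSet, propagate
from dls.preprocess import ConditionPair, ExpressionDataset


@dataclass(frozen=True)
class SignatureGroupSpec:
    """One planted group: genes sharing a template on a feature subset."""

    n_genes: int
    features: tuple[int, ...]
    strength: float = 2.0


@dataclass
class SyntheticSpec:
    n_genes: int
    n_features: int
    groups: list[SignatureGroupSpec]
    noise_sd: float = 0.2
    background_sd: float = 1.0
    n_planted_fns: int = 0
    fdr_low: float = 0.05
    fdr_high_min: float = 0.2
    fdr_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n_pos = sum(g.n_genes for g in self.groups)
        if n_pos + self.n_planted_fns > self.n_genes:
            raise ValueError("more planted genes than genes in the matrix")
        for g in self.groups:
            if not g.features:
                raise ValueError("each group needs a nonempty feature subset")
            if min(g.features) < 0 or max(g.features) >= self.n_features:
                raise ValueError("planted feature subsets must lie in the feature range")
        n_neg = self.n_genes - n_pos
        if self.n_planted_fns > n_neg:
            raise ValueError("n_planted_fns exceeds the negative class size")
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not (0 <= self.fdr_flip_rate <= 1):
            raise ValueError("fdr_flip_rate must lie in [0, 1]")

    @property
    def n_positives(self) -> int:
        return sum(g.n_genes for g in self.groups)


@dataclass
class GroundTruth:
    true_positive_genes: set[str]
    planted_features_per_gene: dict[str, tuple[int, ...]]
    planted_fn_genes: set[str]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, TrainingSet, GroundTruth]:
    """Plant group templates into a noise matrix; fully reproducible from the seed.

    Positive genes carry ``strength * template + N(0, noise_sd)`` on their
    group's features and background noise elsewhere; planted false
    negatives get a group's pattern but a negative label.  FDR cells are
    low (< 0.1) where a pattern was planted and high elsewhere, each
    flipped with probability ``fdr_flip_rate``.
    """
    # independent child streams so e.g. template rejection draws cannot
    # shift the background noise of an otherwise-identical spec
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_tmpl = np.random.default_rng(ss[0])
    rng = np.random.default_rng(ss[1])
    rng_fdr = np.random.default_rng(ss[2])
    genes = _gene_ids(spec.n_genes)
    x_lr = rng.normal(0.0, spec.background_sd or 1e-12, size=(spec.n_genes, spec.n_features))
    if spec.background_sd == 0:
        x_lr[:] = 0.0

    planted = np.zeros((spec.n_genes, spec.n_features), dtype=bool)
    planted_features: dict[str, tuple[int, ...]] = {}

    # template entries are standard normal truncated away from zero so every
    # planted feature carries non-negligible signal (|t| >= 0.5)
    def _template(size: int) -> np.ndarray:
        t = rng_tmpl.normal(0.0, 1.0, size=size)
        while np.any(np.abs(t) < 0.5):
            small = np.abs(t) < 0.5
            t[small] = rng_tmpl.normal(0.0, 1.0, size=int(small.sum()))
        return t

    templates = [_template(len(g.features)) for g in spec.groups]

    row = 0
    positives: list[str] = []
    for g, tmpl in zip(spec.groups, templates):
        idx = np.asarray(g.features, dtype=int)
        for _ in range(g.n_genes):
            gene = genes[row]
            x_lr[row, idx] = g.strength * tmpl + rng.normal(0.0, spec.noise_sd, size=idx.size)
            planted[row, idx] = True
            planted_features[gene] = tuple(sorted(g.features))
            positives.append(gene)
            row += 1

    fn_genes: list[str] = []
    for i in range(spec.n_planted_fns):
        g = spec.groups[i % len(spec.groups)]
        tmpl = templates[i % len(spec.groups)]
        idx = np.asarray(g.features, dtype=int)
        gene = genes[row]
        x_lr[row, idx] = g.strength * tmpl + rng.normal(0.0, spec.noise_sd, size=idx.size)
        planted[row, idx] = True
        planted_features[gene] = tuple(sorted(g.features))
        fn_genes.append(gene)
        row += 1

    low = rng_fdr.uniform(0.0, spec.fdr_low, size=planted.shape)
    high = rng_fdr.uniform(spec.fdr_high_min, 1.0, size=planted.shape)
    flip = rng_fdr.uniform(size=planted.shape) < spec.fdr_flip_rate
    signal = planted ^ flip  # flipped cells swap their FDR regime
    x_fdr = np.where(signal, low, high)

    features = [
        ConditionPair(experiment_id="synth", control=f"c{j}", test=f"t{j}")
        for j in range(spec.n_features)
    ]
    dataset = ExpressionDataset(gene_ids=genes, features=features, x_lr=x_lr, x_fdr=x_fdr)
    training = TrainingSet(
        process_term="SYNTH:BP",
        positives=set(positives),
        negatives=set(genes) - set(positives),
    )
    truth = GroundTruth(
        true_positive_genes=set(positives) | set(fn_genes),
        planted_features_per_gene=planted_features,
        planted_fn_genes=set(fn_genes),
    )
    return dataset, training, truth


def generate_ontology(
    n_terms: int,
    depth: int,
    n_genes: int,
    annotation_density: float = 0.1,
    seed: int = 0,
) -> tuple[OntologyDAG, AnnotationSet]:
    """Random single-root DAG plus random direct annotations.

    Terms are layered to the requested depth; every non-root term gets one
    parent in the previous layer and, with probability 0.3, a second
    parent anywhere above it (making a genuine DAG rather than a tree).
    """
    if not (n_terms >= depth >= 1):
        raise ValueError("need n_terms >= depth >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    root = terms[0]
    edges: set[tuple[str, str]] = set()

    # Assign terms to layers: root alone in layer 0, remaining spread over `depth`.
    layers: list[list[str]] = [[root]]
    rest = terms[1:]
    if rest:
        sizes = np.full(depth, len(rest) // depth)
        sizes[: len(rest) % depth] += 1
        pos = 0
        for s in sizes:
            if s > 0:
                layers.append(rest[pos : pos + s])
                pos += s
    for li in range(1, len(layers)):
        above = [t for layer in layers[:li] for t in layer]
        for t in layers[li]:
            parent = layers[li - 1][rng.integers(len(layers[li - 1]))]
            edges.add((t, parent))
            if len(above) > 1 and rng.random() < 0.3:
                second = above[rng.integers(len(above))]
                if second != t:
                    edges.add((t, second))
    dag = OntologyDAG(terms=set(terms), edges=edges, root=root)

    genes = _gene_ids(n_genes)
    direct: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], str] = {}
    codes = ["EXP", "IDA", "IMP", "IEA"]
    for g in genes:
        for t in terms[1:]:  # direct annotations to the root are uninformative
            if rng.random() < annotation_density:
                direct.setdefault(g, set()).add(t)
                evidence[(g, t)] = codes[rng.integers(len(codes))]
        if g not in direct:  # every gene gets at least one annotation
            t = terms[1 + rng.integers(n_terms - 1)] if n_terms > 1 else root
            direct[g] = {t}
            evidence[(g, t)] = codes[rng.integers(len(codes))]
    ann = propagate(dag, AnnotationSet(direct=direct, evidence=evidence))
    return dag, ann
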