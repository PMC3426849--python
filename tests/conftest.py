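from __future__ import annotations

import numpy as np
import pytest

from dls.ontology import TrainingSet
from dls.preprocess import ConditionPair, ExpressionDataset
from dls.synthetic import SignatureGroupSpec, SyntheticSpec, generate


def make_dataset(x_lr, x_fdr=None, gene_ids=None) -> ExpressionDataset:
    """Wrap raw matrices in an ExpressionDataset with generated ids."""
    x_lr = np.asarray(x_lr, dtype=float)
    if x_fdr is None:
        x_fdr = np.full_like(x_lr, 0.5)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(x_lr.shape[0])]
    features = [
        ConditionPair("exp", f"c{j}", f"t{j}") for j in range(x_lr.shape[1])
    ]
    return ExpressionDataset(gene_ids=gene_ids, features=features, x_lr=x_lr, x_fdr=x_fdr)


@pytest.fixture
def toy_dataset():
    """6 genes x 4 features with hand-set values for oracle checks."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(6, 4))
    fdr = rng.uniform(size=(6, 4))
    return make_dataset(x, fdr)


@pytest.fixture
def toy_training():
    return TrainingSet(
        process_term="T", positives={"g0", "g1", "g2"}, negatives={"g3", "g4", "g5"}
    )


@pytest.fixture(scope="session")
def planted():
    """Medium planted synthetic shared by recovery-style tests (2 groups, clean-ish FDR)."""
    spec = SyntheticSpec(
        n_genes=120,
        n_features=40,
        groups=[
            SignatureGroupSpec(n_genes=12, features=tuple(range(0, 10)), strength=2.0),
            SignatureGroupSpec(n_genes=12, features=tuple(range(20, 30)), strength=2.0),
        ],
        noise_sd=0.1,
        fdr_flip_rate=0.02,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def planted_fns():
    """Planted synthetic with 5 deliberately mislabeled negatives."""
    spec = SyntheticSpec(
        n_genes=100,
        n_features=40,
        groups=[
            SignatureGroupSpec(n_genes=12, features=tuple(range(0, 8)), strength=2.0),
            SignatureGroupSpec(n_genes=12, features=tuple(range(20, 28)), strength=2.0),
        ],
        noise_sd=0.1,
        n_planted_fns=5,
        fdr_flip_rate=0.02,
        seed=23,
    )
    return generate(spec)
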