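import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dls.ontology import TrainingSet
from dls.signatures import (
    SignatureParams,
    abs_cosine,
    bootstrap_discard,
    coexpr_components,
    ess,
    ess_from_components,
    signfs,
    soft_threshold,
    train,
)

from _oracles import brute_coexpr_components, brute_ess
from conftest import make_dataset


class TestAbsCosine:
    def test_collinear(self):
        assert abs_cosine([1, 2], [2, 4], [0, 1]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert abs_cosine([1, 0], [0, 1], [0, 1]) == pytest.approx(0.0)

    def test_hand_dot_products(self):
        assert abs_cosine([1, 1], [1, -1], [0, 1]) == pytest.approx(0.0)
        assert abs_cosine([3, 4], [4, 3], [0, 1]) == pytest.approx(24 / 25)

    def test_zero_norm_returns_zero(self):
        assert abs_cosine([0, 0], [1, 1], [0, 1]) == 0.0

    def test_empty_features_error(self):
        with pytest.raises(ValueError):
            abs_cosine([1], [1], [])

    def test_restriction_ignores_other_features(self):
        assert abs_cosine([1, 99], [1, -99], [0]) == pytest.approx(1.0)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_scale_invariance(self, x, y, c):
        f = [0, 1, 2]
        assert abs_cosine(x, y, f) == pytest.approx(abs_cosine(y, x, f))
        scaled = [c * v for v in x]
        assert abs_cosine(scaled, y, f) == pytest.approx(abs_cosine(x, y, f), abs=1e-9)

    def test_one_iff_collinear(self):
        assert abs_cosine([1, 2, 3], [-2, -4, -6], [0, 1, 2]) == pytest.approx(1.0)
        assert abs_cosine([1, 2, 3], [1, 2, 4], [0, 1, 2]) < 1.0


class TestSoftThreshold:
    def test_strong_coexpression_above_half(self):
        assert soft_threshold(0.8) > 0.5

    def test_weak_coexpression_near_zero(self):
        # 1/(1 + e^{30*0.15})
        assert soft_threshold(0.6) == pytest.approx(1 / (1 + math.exp(4.5)))
        assert soft_threshold(0.6) <= 0.05

    def test_midpoint_is_half(self):
        assert soft_threshold(0.75) == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0, 1, 101)
        vals = soft_threshold(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 0) & (vals <= 1))


class TestCoexprComponents:
    def test_limiting_case_identical_positives(self):
        x = np.zeros((6, 3))
        x[0] = x[1] = x[2] = x[3] = [1.0, 2.0, -1.0]
        x[4] = [2.0, -1.0, 0.0]
        x[5] = [-1.0, 0.5, 2.0]  # orthogonal-ish to gene 0
        ds = make_dataset(x)
        tr = TrainingSet("T", {"g0", "g1", "g2", "g3"}, {"g4", "g5"})
        c_pos, c_neg = coexpr_components("g0", [0, 1, 2], ds, tr)
        assert c_pos == pytest.approx(3 * soft_threshold(1.0))
        assert c_neg < 0.02

    def test_empty_negative_set(self, toy_dataset):
        tr = TrainingSet("T", {"g0", "g1"}, set())
        _, c_neg = coexpr_components("g0", [0, 1], toy_dataset, tr)
        assert c_neg == 0.0

    def test_no_positive_partners_warns(self, toy_dataset):
        tr = TrainingSet("T", {"g0"}, {"g3"})
        c_pos, _ = coexpr_components("g0", [0, 1], toy_dataset, tr)
        assert c_pos == 0.0

    def test_matches_brute_force_oracle_toy(self, toy_dataset, toy_training):
        params = SignatureParams()
        for gene in ("g0", "g1", "g4"):
            got = coexpr_components(gene, [0, 2, 3], toy_dataset, toy_training, params)
            want = brute_coexpr_components(gene, [0, 2, 3], toy_dataset, toy_training, params)
            assert got == pytest.approx(want)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        m = int(rng.integers(3, 10))
        ds = make_dataset(rng.normal(size=(n, m)))
        genes = list(ds.gene_ids)
        k = n // 3
        tr = TrainingSet("T", set(genes[:k]), set(genes[k : 2 * k]))
        params = SignatureParams()
        feats = sorted(rng.choice(m, size=min(3, m), replace=False).tolist())
        for gene in genes[: k + 2]:
            got = coexpr_components(gene, feats, ds, tr, params)
            want = brute_coexpr_components(gene, feats, ds, tr, params)
            assert got == pytest.approx(want)


class TestESS:
    def test_plug_in_example(self):
        p = SignatureParams()  # alpha_halfsize = 5
        assert ess_from_components(2.0, 2.0, 5, p) == pytest.approx(0.25, abs=1e-6)

    def test_zero_positive_component(self):
        assert ess_from_components(0.0, 3.0, 4, SignatureParams()) == 0.0

    def test_limit_no_negatives_many_features(self):
        p = SignatureParams()
        assert ess_from_components(5.0, 0.0, 10_000, p) == pytest.approx(1.0, abs=1e-3)

    def test_beta_zero_ignores_negatives(self):
        p0 = SignatureParams(beta=0.0)
        assert ess_from_components(2.0, 100.0, 5, p0) == pytest.approx(
            ess_from_components(2.0, 0.0, 5, p0)
        )

    @given(
        st.floats(0, 50), st.floats(0, 50), st.integers(1, 100),
        st.floats(0, 5), st.floats(0.1, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_unit_interval(self, c_pos, c_neg, n, beta, beta2):
        p = SignatureParams(beta=beta)
        v = ess_from_components(c_pos, c_neg, n, p)
        assert 0.0 <= v <= 1.0
        # monotone decreasing in beta at fixed components
        p_hi = SignatureParams(beta=beta + beta2)
        assert ess_from_components(c_pos, c_neg, n, p_hi) <= v + 1e-12

    def test_full_ess_matches_oracle(self, toy_dataset, toy_training):
        params = SignatureParams()
        got = ess("g1", [0, 1, 3], toy_dataset, toy_training, params)
        assert got == pytest.approx(
            brute_ess("g1", [0, 1, 3], toy_dataset, toy_training, params)
        )


def _anti_discriminative_toy():
    """Feature 2 links the gene to the negatives; {0, 1} link it to the positives."""
    x = np.array(
        [
            [1.0, 1.0, 1.0],   # g0: gene under search
            [1.0, 1.0, -1.0],  # g1: positive
            [1.0, 1.0, -1.0],  # g2: positive
            [0.0, 0.0, 1.0],   # g3: negative
            [0.0, 0.0, 1.0],   # g4: negative
        ]
    )
    ds = make_dataset(x, np.full_like(x, 0.01))
    tr = TrainingSet("T", {"g0", "g1", "g2"}, {"g3", "g4"})
    return ds, tr


class TestSignFS:
    def test_anti_discriminative_feature_removed(self):
        ds, tr = _anti_discriminative_toy()
        params = SignatureParams(candidate_frac=1.0, fdr_init=1.0)
        sig = signfs("g0", ds, tr, params)
        assert sig.features == (0, 1)
        # hand-scored best subset {0,1}: alpha(2)=2/7, c_pos ~ 2, c_neg ~ 0
        assert sig.ess == pytest.approx(2 / 7 * soft_threshold(1.0), abs=1e-3)

    def test_hand_scored_subsets_confirm_optimum(self):
        ds, tr = _anti_discriminative_toy()
        params = SignatureParams(candidate_frac=1.0, fdr_init=1.0)
        scores = {
            feats: brute_ess("g0", list(feats), ds, tr, params)
            for r in (1, 2, 3)
            for feats in itertools.combinations(range(3), r)
        }
        assert max(scores, key=scores.get) == (0, 1)

    def test_trace_strictly_increasing_and_final_geq_initial(self, planted):
        ds, tr, _ = planted
        for gene in sorted(tr.positives)[:6]:
            sig = signfs(gene, ds, tr, SignatureParams())
            trace = sig.trace
            assert all(b > a for a, b in zip(trace, trace[1:]))
            assert sig.ess >= trace[0]

    def test_empty_seed_yields_invalid_signature(self):
        x = np.random.default_rng(0).normal(size=(5, 4))
        ds = make_dataset(x, np.full((5, 4), 0.9))  # nothing significant
        tr = TrainingSet("T", {"g0", "g1"}, {"g2", "g3"})
        sig = signfs("g0", ds, tr, SignatureParams())
        assert sig.features == () and sig.ess == 0.0 and not sig.valid

    def test_greedy_never_beats_exhaustive_max(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(8, 10))
        x[0, :4] = x[1, :4] = x[2, :4] = [2.0, -1.0, 1.5, 0.5]
        fdr = rng.uniform(0.2, 1.0, size=(8, 10))
        fdr[:, :4] = 0.01
        ds = make_dataset(x, fdr)
        tr = TrainingSet("T", {"g0", "g1", "g2"}, {"g3", "g4", "g5", "g6", "g7"})
        params = SignatureParams(candidate_frac=1.0, fdr_init=0.1)
        sig = signfs("g0", ds, tr, params)
        global_max = max(
            brute_ess("g0", list(feats), ds, tr, params)
            for r in range(1, 11)
            for feats in itertools.combinations(range(10), r)
        )
        assert sig.ess <= global_max + 1e-9
        assert sig.ess >= sig.trace[0]

    def test_planted_feature_recovery(self, planted):
        ds, tr, truth = planted
        jaccards = []
        for gene in sorted(tr.positives):
            sig = signfs(gene, ds, tr, SignatureParams())
            got = set(sig.features)
            want = set(truth.planted_features_per_gene[gene])
            jaccards.append(len(got & want) / len(got | want))
        assert np.mean([j >= 0.8 for j in jaccards]) >= 0.9


class TestBootstrapDiscard:
    def test_empty_when_below_floor(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=(6, 8)))
        tr = TrainingSet("T", {"g0", "g1"}, {"g2", "g3", "g4", "g5"})
        params = SignatureParams(bootstrap=True, boot_min_coexpr=0.999, boot_top_k=4)
        assert bootstrap_discard("g0", range(8), ds, tr, params) == frozenset()

    def test_top_k_of_those_above_floor(self):
        # negatives with cosines 0.99, 0.97, 0.95, 0.93, 0.91 against g0=(1,0)
        def vec(c):
            t = math.sqrt(1 / c**2 - 1)
            return [1.0, t]

        x = np.array([[1.0, 0.0], [1.0, 0.0]] + [vec(c) for c in (0.99, 0.97, 0.95, 0.93, 0.91)])
        ds = make_dataset(x)
        tr = TrainingSet("T", {"g0", "g1"}, {"g2", "g3", "g4", "g5", "g6"})
        params = SignatureParams(bootstrap=True, boot_min_coexpr=0.8, boot_top_k=3)
        assert bootstrap_discard("g0", [0, 1], ds, tr, params) == {"g2", "g3", "g4"}

    def test_default_top_k_scales_with_negatives(self):
        p = SignatureParams()
        assert p.effective_boot_top_k(50) == 1
        assert p.effective_boot_top_k(350) == 4

    def test_planted_false_negatives_usually_discarded(self, planted_fns):
        ds, tr, truth = planted_fns
        params = SignatureParams(bootstrap=True, boot_top_k=10)
        group0 = tuple(range(0, 8))
        fns_group0 = {
            g for g in truth.planted_fn_genes
            if truth.planted_features_per_gene[g] == group0
        }
        positives_group0 = [
            g for g in sorted(tr.positives)
            if truth.planted_features_per_gene[g] == group0
        ]
        hit_rates = []
        for gene in positives_group0:
            discarded = bootstrap_discard(gene, group0, ds, tr, params)
            hit_rates.append(len(fns_group0 & discarded) / len(fns_group0))
        assert np.mean(hit_rates) >= 0.9


class TestTrain:
    def test_planted_positives_mostly_valid(self, planted):
        ds, tr, _ = planted
        model = train(ds, tr, SignatureParams())
        assert len(model.valid_signatures) >= 0.9 * len(tr.positives)

    def test_shuffled_labels_kill_valid_signatures(self, planted):
        ds, tr, _ = planted
        rng = np.random.default_rng(0)
        genes = list(rng.permutation(ds.gene_ids))
        shuffled = TrainingSet("T", set(genes[: len(tr.positives)]),
                               set(genes[len(tr.positives):]))
        model = train(ds, shuffled, SignatureParams())
        assert len(model.valid_signatures) <= 0.1 * len(tr.positives)

    def test_duplicate_gene_gets_identical_signature(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 6))
        x[:3, :3] = [1.0, -2.0, 1.5]  # shared pattern for g0..g2
        x[7] = x[0]  # duplicate of g0
        fdr = rng.uniform(0.3, 1.0, size=(8, 6))
        fdr[:3, :3] = 0.01
        fdr[7] = fdr[0]
        ds = make_dataset(x, fdr)
        tr = TrainingSet("T", {"g0", "g1", "g2", "g7"}, {"g3", "g4", "g5"})
        model = train(ds, tr, SignatureParams())
        by_gene = {s.gene: s for s in model.signatures}
        assert by_gene["g0"].features == by_gene["g7"].features
        assert by_gene["g0"].ess == pytest.approx(by_gene["g7"].ess)

    def test_deterministic(self, planted):
        ds, tr, _ = planted
        m1 = train(ds, tr, SignatureParams())
        m2 = train(ds, tr, SignatureParams())
        assert [(s.gene, s.features, s.ess) for s in m1.signatures] == [
            (s.gene, s.features, s.ess) for s in m2.signatures
        ]


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_valid": 0.0},
            {"tau_valid": 1.0},
            {"candidate_frac": 0.0},
            {"candidate_frac": 1.5},
            {"beta": -1.0},
            {"alpha_halfsize": 0.0},
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SignatureParams(**kwargs)
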