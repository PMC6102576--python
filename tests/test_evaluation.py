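import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from rmvspc import (
    ExpressionView,
    HyperParams,
    Network,
    module_activity,
    module_score,
    nmi,
    permutation_significance,
)
from rmvspc.data_model import ModulePartition
from rmvspc.evaluation import empirical_p_values
from statsmodels.stats.multitest import multipletests


def _partition(labels):
    labels = np.asarray(labels)
    return ModulePartition(labels, k=int(labels.max()))


class TestNmi:
    def test_identity_up_to_relabeling_scores_one(self):
        P = _partition([1, 1, 2, 2, 3, 3])
        Q = _partition([3, 3, 1, 1, 2, 2])
        assert nmi(P, Q) == pytest.approx(1.0)

    def test_exact_independence_scores_zero(self):
        P = _partition([1, 1, 2, 2])
        Q = _partition([1, 2, 1, 2])
        assert nmi(P, Q) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_entropy_implementation(self, rng):
        # arithmetic-mean NMI computed from entropies is algebraically the
        # same quantity; sklearn provides that route independently
        for _ in range(100):
            n = 20
            a = _compact(rng.integers(1, 5, size=n))
            b = _compact(rng.integers(1, 4, size=n))
            ours = nmi(_partition(a), _partition(b))
            ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_symmetry_and_range(self, rng):
        a = _compact(rng.integers(1, 4, size=30))
        b = _compact(rng.integers(1, 6, size=30))
        P, Q = _partition(a), _partition(b)
        assert nmi(P, Q) == pytest.approx(nmi(Q, P), abs=1e-14)
        assert 0.0 <= nmi(P, Q) <= 1.0 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(_partition([1, 2]), _partition([1, 2, 1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(1, 3), min_size=6, max_size=20),
        perm_seed=st.integers(0, 1000),
    )
    def test_invariant_under_label_permutation(self, a, perm_seed):
        a = _compact(np.array(a))
        k = int(a.max())
        if k < 2:
            return
        rng = np.random.default_rng(perm_seed)
        relabel = rng.permutation(k) + 1
        b = relabel[a - 1]
        rng2 = np.random.default_rng(0)
        other = _compact(rng2.integers(1, 3, size=a.size))
        P, Pr = _partition(a), _partition(b)
        Q = _partition(other)
        assert nmi(P, Pr) == pytest.approx(1.0)
        assert nmi(P, Q) == pytest.approx(nmi(Pr, Q), abs=1e-12)

    def test_single_cluster_vs_single_cluster_is_one(self):
        P = ModulePartition(np.array([1, 1, 1]), 1)
        assert nmi(P, P) == pytest.approx(1.0)


def _compact(labels):
    """Relabel onto 1..k so every module index is populated."""
    uniq = sorted(set(labels.tolist()))
    remap = {u: i for i, u in enumerate(uniq, start=1)}
    return np.array([remap[v] for v in labels])


class TestModuleScore:
    def test_duplicate_gene_scores_one(self, rng):
        x = rng.normal(size=10)
        expr = np.column_stack([x, x])
        assert module_score(expr, [0, 1]) == pytest.approx(1.0)

    def test_negated_gene_scores_minus_one(self, rng):
        x = rng.normal(size=10)
        expr = np.column_stack([x, -x])
        assert module_score(expr, [0, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_pairwise_mean(self):
        expr = np.array(
            [
                [1.0, 2.0, 0.5, 3.0],
                [2.0, 1.5, 1.0, 2.0],
                [3.0, 3.5, 0.0, 1.0],
                [4.0, 2.5, 2.0, 5.0],
                [5.0, 4.0, 1.5, 4.0],
            ]
        )
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        expected = np.mean(
            [np.corrcoef(expr[:, i], expr[:, j])[0, 1] for i, j in pairs]
        )
        assert module_score(expr, [0, 1, 2, 3]) == pytest.approx(expected)

    def test_constant_gene_pairs_contribute_zero(self, rng):
        x = rng.normal(size=8)
        expr = np.column_stack([x, x, np.ones(8)])
        # pairs: (0,1)=1, (0,2)=0, (1,2)=0 -> mean 1/3
        assert module_score(expr, [0, 1, 2]) == pytest.approx(1.0 / 3.0)

    def test_too_small_module_rejected(self, rng):
        with pytest.raises(ValueError):
            module_score(rng.normal(size=(5, 3)), [0])


class TestEmpiricalPAndBH:
    def test_add_one_estimator(self, rng):
        null = rng.uniform(size=19)
        observed = np.array([null.max() + 1.0])
        assert empirical_p_values(observed, null)[0] == pytest.approx(0.05)

    def test_bh_step_up_hand_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_bh_q_dominates_p_and_is_monotone(self, rng):
        p = np.sort(rng.uniform(size=12))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.all(q >= p - 1e-12)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


def _noise_views(rng, n_genes, n_samples, m=1):
    return [
        ExpressionView(
            stage_id=s + 1,
            values=rng.normal(size=(n_samples, n_genes)),
            gene_ids=[f"g{i}" for i in range(n_genes)],
            sample_ids=[f"s{s}_{j}" for j in range(n_samples)],
        )
        for s in range(m)
    ]


class TestPermutationSignificance:
    def test_null_p_values_are_approximately_uniform(self, rng):
        # pure noise: the observed modules are exchangeable with permuted
        # ones, so p-values should be uniform within binomial tolerance
        n_modules, genes_per = 30, 3
        n_genes = n_modules * genes_per
        views = _noise_views(rng, n_genes, n_samples=12)
        net = Network(np.zeros((n_genes, n_genes)), views[0].gene_ids)
        labels = np.repeat(np.arange(1, n_modules + 1), genes_per)
        part = ModulePartition(labels, n_modules)
        sig = permutation_significance(
            views, net, part, HyperParams(k=n_modules),
            n_perm=200, seed=0, refit=False,
        )
        frac = float(np.mean(sig.p_values <= 0.1))
        # binomial(30, 0.1): 0.1 +/- 3 * sqrt(0.1 * 0.9 / 30)
        assert frac <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / 30)

    def test_refit_pipeline_runs_and_flags_coherent_modules(self, toy_views,
                                                            toy_network):
        from rmvspc import detect_modules, fit
        rep = fit(toy_views, toy_network, HyperParams.equal(1.0, k=2))
        part = detect_modules(rep.consensus, k=2, seed=0)
        sig = permutation_significance(
            toy_views, toy_network, part, HyperParams.equal(1.0, k=2),
            n_perm=10, seed=0, refit=True,
        )
        assert sig.p_values.shape == (2,)
        assert np.all((sig.p_values > 0) & (sig.p_values <= 1))
        assert np.all(sig.q_values >= sig.p_values - 1e-12)
        # the toy blocks are strongly co-expressed: top of the null easily
        assert np.all(sig.module_scores > sig.null_scores.mean())

    def test_invalid_n_perm_rejected(self, toy_views, toy_network):
        part = ModulePartition(np.array([1] * 4 + [2] * 4), 2)
        with pytest.raises(ValueError):
            permutation_significance(
                toy_views, toy_network, part, n_perm=0, seed=0
            )


class TestModuleActivity:
    def test_single_gene_module_is_its_zscore(self, rng):
        expr = rng.normal(size=(6, 3)) * 3 + 1
        part = ModulePartition(np.array([1, 2, 2]), 2)
        feats = module_activity(expr, part)
        z0 = (expr[:, 0] - expr[:, 0].mean()) / expr[:, 0].std()
        np.testing.assert_allclose(feats[:, 0], z0)

    def test_feature_columns_have_zero_sample_mean(self, rng):
        expr = rng.normal(size=(9, 6))
        part = ModulePartition(np.array([1, 1, 2, 2, 2, 1]), 2)
        feats = module_activity(expr, part)
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-12)

    def test_matches_hand_computed_average(self):
        expr = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        part = ModulePartition(np.array([1, 1]), 1)
        z = (expr - expr.mean(0)) / expr.std(0)
        np.testing.assert_allclose(
            module_activity(expr, part)[:, 0], z.mean(axis=1)
        )

    def test_invariant_to_affine_rescaling_of_one_gene(self, rng):
        expr = rng.normal(size=(7, 4))
        part = ModulePartition(np.array([1, 1, 2, 2]), 2)
        scaled = expr.copy()
        scaled[:, 2] = 5.0 * scaled[:, 2] - 3.0
        np.testing.assert_allclose(
            module_activity(expr, part), module_activity(scaled, part),
            atol=1e-12,
        )
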