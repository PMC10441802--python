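import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterbma.core import (
    AllocationMatrix,
    SimilarityMatrix,
    allocation_to_similarity,
    labels_to_allocation,
)
from clusterbma.evaluation import adjusted_rand_index
from clusterbma.ssmf import (
    SsmfConfig,
    allocation_uncertainty,
    choose_k_bma,
    factorise,
    project_rows_to_simplex,
    prune_empty_clusters,
    ssmf_factorise,
)


def _block_similarity(labels, k):
    return allocation_to_similarity(labels_to_allocation(labels, k))


class TestSimplexProjection:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_projection_lands_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=3.0, size=(15, 4))
        p = project_rows_to_simplex(a)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_on_simplex_points(self, rng):
        a = rng.dirichlet(np.ones(3), size=10)
        np.testing.assert_allclose(project_rows_to_simplex(a), a, atol=1e-12)


class TestFactorise:
    def test_recovers_hard_clustering_exactly(self):
        labels = np.repeat([1, 2, 3], 15)
        sim = _block_similarity(labels, 3)
        # unregularised: the exact factorisation is the global optimum
        fit = factorise(sim, SsmfConfig(k_bma=3, seed=0, l2_lambda=0.0))
        assert adjusted_rand_index(labels, fit.allocation.hard_labels()) == 1.0
        resid = fit.allocation.values @ fit.allocation.values.T - sim.values
        np.fill_diagonal(resid, 0.0)
        assert np.abs(resid).max() < 1e-6
        # the default L2 penalty biases rows off the vertices only at O(lambda/n_k)
        fit_reg = factorise(sim, SsmfConfig(k_bma=3, seed=0))
        assert adjusted_rand_index(labels, fit_reg.allocation.hard_labels()) == 1.0
        assert fit_reg.allocation.values.max(axis=1).min() > 0.99

    def test_all_ones_consensus_empties_second_column(self):
        sim = SimilarityMatrix(np.ones((12, 12)))
        alloc = ssmf_factorise(sim, SsmfConfig(k_bma=2, seed=0))
        col_mass = np.sort(alloc.values.sum(axis=0))
        assert col_mass[0] < 0.05 * 12
        assert col_mass[1] > 0.95 * 12

    def test_two_point_anti_block(self):
        sim = SimilarityMatrix(np.eye(2))
        alloc = ssmf_factorise(sim, SsmfConfig(k_bma=2, seed=1, l2_lambda=0.0))
        np.testing.assert_allclose(
            np.sort(alloc.values, axis=0), [[0, 0], [1, 1]], atol=1e-6
        )

    def test_objective_trace_monotone_nonincreasing(self, rng):
        sim = _block_similarity(np.repeat([1, 2], 10), 2)
        noisy = np.clip(sim.values + rng.normal(scale=0.05, size=(20, 20)), 0, 1)
        noisy = 0.5 * (noisy + noisy.T)
        np.fill_diagonal(noisy, 1.0)
        fit = factorise(SimilarityMatrix(noisy), SsmfConfig(k_bma=2, seed=3))
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-12)

    def test_rows_on_simplex(self):
        sim = _block_similarity(np.repeat([1, 2, 3], 8), 3)
        alloc = ssmf_factorise(sim, SsmfConfig(k_bma=3, seed=5))
        np.testing.assert_allclose(alloc.values.sum(axis=1), 1.0, atol=1e-8)

    def test_deterministic_given_seed(self):
        sim = _block_similarity(np.repeat([1, 2], 12), 2)
        a1 = ssmf_factorise(sim, SsmfConfig(k_bma=2, seed=9)).values
        a2 = ssmf_factorise(sim, SsmfConfig(k_bma=2, seed=9)).values
        np.testing.assert_array_equal(a1, a2)

    def test_permutation_equivariance(self, rng):
        labels = np.repeat([1, 2, 3], 6)
        sim = _block_similarity(labels, 3)
        perm = rng.permutation(18)
        sim_p = SimilarityMatrix(sim.values[np.ix_(perm, perm)])
        a = ssmf_factorise(sim, SsmfConfig(k_bma=3, seed=2)).values
        a_p = ssmf_factorise(sim_p, SsmfConfig(k_bma=3, seed=2)).values
        # compare label-invariantly via implied similarity matrices
        s1 = (a @ a.T)[np.ix_(perm, perm)]
        s2 = a_p @ a_p.T
        np.testing.assert_allclose(s1, s2, atol=1e-5)

    def test_nonconvergence_warns_but_returns(self):
        sim = _block_similarity(np.repeat([1, 2, 3], 10), 3)
        cfg = SsmfConfig(k_bma=3, seed=0, max_iter=2, tol=1e-15, n_restarts=1)
        with pytest.warns(RuntimeWarning, match="SSMF"):
            alloc = ssmf_factorise(sim, cfg)
        assert alloc.n_points == 30

    def test_k_bma_larger_than_n_rejected(self):
        sim = SimilarityMatrix(np.eye(2))
        with pytest.raises(ValueError):
            ssmf_factorise(sim, SsmfConfig(k_bma=3, seed=0))


class TestPrune:
    def test_zero_column_removed(self):
        a = AllocationMatrix(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        pruned = prune_empty_clusters(a, 0.01)
        assert pruned.n_clusters == 2
        np.testing.assert_array_equal(pruned.values, [[1, 0], [0, 1]])

    def test_identity_when_no_column_below_threshold(self):
        a = AllocationMatrix(np.array([[0.5, 0.5], [0.4, 0.6]]))
        assert prune_empty_clusters(a, 0.01) is a

    def test_two_cluster_consensus_with_three_columns_prunes_to_two(self):
        labels = np.repeat([1, 2], 25)
        sim = _block_similarity(labels, 2)
        fit = factorise(sim, SsmfConfig(k_bma=3, seed=4))
        pruned = prune_empty_clusters(fit.allocation, 0.01)
        assert pruned.n_clusters == 2
        assert adjusted_rand_index(labels, pruned.hard_labels()) == 1.0

    def test_all_columns_pruned_rejected(self):
        a = AllocationMatrix(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            prune_empty_clusters(a, 0.9)


class TestUncertainty:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.3, 0.2], 0.5),
            ([0.25, 0.25, 0.25, 0.25], 0.75),
        ],
    )
    def test_examples(self, row, expected):
        alloc = AllocationMatrix(np.array([row]))
        assert allocation_uncertainty(alloc)[0] == pytest.approx(expected)

    def test_bounded_by_one_minus_inverse_k(self, rng):
        alloc = AllocationMatrix(rng.dirichlet(np.ones(4), size=30))
        u = allocation_uncertainty(alloc)
        assert np.all(u >= 0) and np.all(u <= 0.75 + 1e-12)


class TestChooseKBma:
    @pytest.mark.parametrize(
        "ks,strategy,expected",
        [((3, 2), "max_k", 3), ((5, 5, 5), "max_k", 5), ((4, 3), "max_k_plus", 5)],
    )
    def test_strategies(self, ks, strategy, expected):
        assert choose_k_bma(ks, strategy) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_k_bma([])
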