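"""KL-NMF correctness: exact factorizations, monotone updates, consensus."""

import numpy as np
import pandas as pd
import pytest

from immunophen import ExpressionMatrix, nmf_consensus, nmf_factorize, top_weighted_genes
from immunophen.nmf import NMFResult, kl_divergence


def _random_positive(rng, n, m):
    return rng.uniform(0.1, 5.0, (n, m))


class TestFactorize:
    def test_rank_one_exact_factorization(self):
        rng = np.random.default_rng(0)
        V = np.outer(rng.uniform(0.5, 2.0, 20), rng.uniform(0.5, 2.0, 10))
        res = nmf_factorize(V, k=1, n_restarts=3, max_iter=2000, tol=1e-12, seed=0)
        assert res.divergence < 1e-6

    def test_divergence_trace_non_increasing(self):
        rng = np.random.default_rng(1)
        V = _random_positive(rng, 25, 12)
        res = nmf_factorize(V, k=3, n_restarts=1, max_iter=300, tol=0.0, seed=1)
        diffs = np.diff(res.trace)
        assert (diffs <= 1e-8 * np.abs(res.trace[:-1]) + 1e-10).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_best_of_restarts_never_worse_than_single(self, seed):
        rng = np.random.default_rng(10 + seed)
        V = _random_positive(rng, 20, 10)
        multi = nmf_factorize(V, k=3, n_restarts=10, max_iter=200, tol=1e-7, seed=seed)
        single = nmf_factorize(V, k=3, n_restarts=1, max_iter=200, tol=1e-7, seed=seed)
        assert multi.divergence <= single.divergence + 1e-10

    def test_recorded_divergence_matches_factors(self):
        rng = np.random.default_rng(3)
        V = _random_positive(rng, 15, 8)
        res = nmf_factorize(V, k=2, n_restarts=2, max_iter=300, tol=1e-8, seed=3)
        assert res.divergence == pytest.approx(
            kl_divergence(V, res.W @ res.H), rel=1e-8
        )

    def test_scale_normalization_preserves_product(self):
        rng = np.random.default_rng(4)
        V = _random_positive(rng, 15, 8)
        res = nmf_factorize(V, k=2, n_restarts=1, max_iter=200, tol=1e-7, seed=4)
        np.testing.assert_allclose(res.W.sum(axis=0), 1.0, atol=1e-10)
        # the fit's divergence is the product's divergence, i.e. WH unchanged
        assert kl_divergence(V, res.W @ res.H) == pytest.approx(res.divergence, rel=1e-8)

    def test_nonnegativity_of_factors(self):
        rng = np.random.default_rng(5)
        res = nmf_factorize(_random_positive(rng, 12, 9), k=2, n_restarts=1,
                            max_iter=100, tol=1e-6, seed=5)
        assert (res.W >= 0).all() and (res.H >= 0).all()

    def test_planted_factorization_reached(self):
        # with a feasible planted (W*, H*) the optimizer must do at least as
        # well as the planted solution up to the noise floor
        rng = np.random.default_rng(6)
        Wt = rng.uniform(0.1, 1.0, (30, 3))
        Ht = rng.uniform(0.1, 1.0, (3, 15))
        noise = rng.uniform(0, 0.01, (30, 15))
        V = Wt @ Ht + noise
        planted_div = kl_divergence(V, Wt @ Ht)
        res = nmf_factorize(V, k=3, n_restarts=10, max_iter=2000, tol=1e-10, seed=6)
        assert res.divergence <= planted_div * 1.05 + 1e-9

    def test_matches_independent_mu_solver(self):
        # sklearn's multiplicative-update KL solver is an independent
        # implementation of the same objective; best-restart divergences
        # must agree closely on a small instance
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(7)
        V = _random_positive(rng, 30, 15)
        ours = nmf_factorize(V, k=3, n_restarts=10, max_iter=2000, tol=1e-9, seed=7)
        sk = SkNMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                   init="random", max_iter=2000, tol=1e-9, random_state=0)
        Wsk = sk.fit_transform(V)
        sk_div = kl_divergence(V, Wsk @ sk.components_)
        assert ours.divergence == pytest.approx(sk_div, rel=0.01)

    def test_input_validation(self):
        V = np.ones((5, 4))
        with pytest.raises(ValueError):
            nmf_factorize(-V, k=1)
        with pytest.raises(ValueError):
            nmf_factorize(V, k=0)
        with pytest.raises(ValueError):
            nmf_factorize(V, k=4)  # k must be < min(n, m)


def _block_matrix(rng):
    """Two sample blocks with disjoint active gene sets."""
    V = np.full((20, 12), 1e-6)
    V[:10, :6] = rng.uniform(1.0, 2.0, (10, 6))
    V[10:, 6:] = rng.uniform(1.0, 2.0, (10, 6))
    return V


class TestConsensus:
    def test_two_planted_blocks_give_perfect_consensus(self):
        rng = np.random.default_rng(8)
        cons = nmf_consensus(_block_matrix(rng), k=2, n_runs=10, seed=8, max_iter=300)
        C = cons.consensus
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)
        assert C[:6, :6].min() == 1.0 and C[6:, 6:].min() == 1.0
        assert C[:6, 6:].max() == 0.0
        assert cons.cophenetic == pytest.approx(1.0)
        labels = cons.labels
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        V = _block_matrix(rng)
        perm = np.random.default_rng(1).permutation(V.shape[1])
        a = nmf_consensus(V, k=2, n_runs=8, seed=9, max_iter=300)
        b = nmf_consensus(V[:, perm], k=2, n_runs=8, seed=9, max_iter=300)
        # partitions agree up to relabeling
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_consensus_entries_in_unit_interval(self):
        rng = np.random.default_rng(10)
        V = rng.uniform(0.1, 2.0, (15, 10))
        cons = nmf_consensus(V, k=2, n_runs=5, seed=10, max_iter=100)
        assert cons.consensus.min() >= 0.0 and cons.consensus.max() <= 1.0
        assert 0.0 <= cons.cophenetic <= 1.0


class TestTopWeightedGenes:
    def _result(self):
        W = np.array([[0.5, 0.9], [0.5, 0.3], [0.4, 0.3], [0.1, 0.1]])
        return NMFResult(W=W, H=np.ones((2, 3)), k=2, divergence=0.0, n_iter=1,
                         seed=0, gene_ids=["DELTA", "BRAVO", "ALPHA", "ECHO"])

    def test_sorted_descending_with_lexicographic_ties(self):
        res = self._result()
        # factor 2 weights: DELTA .9, BRAVO .3, ALPHA .3, ECHO .1
        assert top_weighted_genes(res, factor=2, n=3) == ["DELTA", "ALPHA", "BRAVO"]

    def test_exact_length_and_default_size(self):
        rng = np.random.default_rng(11)
        ids = [f"G{i:04d}" for i in range(200)]
        res = NMFResult(W=rng.uniform(0, 1, (200, 3)), H=np.ones((3, 5)), k=3,
                        divergence=0.0, n_iter=1, seed=0, gene_ids=ids)
        assert len(top_weighted_genes(res, factor=1, n=150)) == 150

    def test_factor_out_of_range(self):
        with pytest.raises(ValueError):
            top_weighted_genes(self._result(), factor=3, n=2)


def test_accepts_expression_matrix_and_keeps_ids(mini_cohort):
    sub = ExpressionMatrix(np.log2(mini_cohort.expression.data.iloc[:50, :30] + 1))
    res = nmf_factorize(sub, k=2, n_restarts=1, max_iter=50, tol=1e-4, seed=0)
    assert res.gene_ids == sub.gene_ids
    assert res.sample_ids == sub.sample_ids
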