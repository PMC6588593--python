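import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointphy import (ErrorModel, MutationTree, SingleCellMatrix,
                      attachment_loglik, attachment_posterior,
                      doublet_mixture_likelihood,
                      marginal_singlet_likelihood, random_mutation_tree,
                      score_sc)
from jointphy.simulate import SimulationConfig, sample_cells, simulate_ground_truth

from .oracles import (brute_doublet, brute_sc_score, brute_singlet,
                      mutation_tree_from_singleton_clonal)

THETA = ErrorModel(alpha=0.01, beta=0.2)


class TestAttachmentLoglik:
    def test_single_mutation_cases(self):
        tree = MutationTree((2,))
        assert attachment_loglik(np.array([1]), tree, THETA, 1) == \
            pytest.approx(np.log(1 - 0.2))
        assert attachment_loglik(np.array([1]), tree, THETA, 2) == \
            pytest.approx(np.log(0.01))
        assert attachment_loglik(np.array([0]), tree, THETA, 1) == \
            pytest.approx(np.log(0.2))
        assert attachment_loglik(np.array([0]), tree, THETA, 2) == \
            pytest.approx(np.log(0.99))

    def test_missing_entries_neutral(self, chain3):
        col = np.array([-1, -1, -1])
        for node in range(1, 5):
            assert attachment_loglik(col, chain3, THETA, node) == 0.0


class TestSingletMarginal:
    def test_hand_enumeration_n1(self):
        tree = MutationTree((2,))
        got = marginal_singlet_likelihood(np.array([1]), tree, THETA)
        assert got == pytest.approx((0.01 + 0.8) / 2)

    def test_all_na_column_is_one(self, chain3):
        assert marginal_singlet_likelihood(np.array([-1, -1, -1]), chain3,
                                           THETA) == pytest.approx(1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 5))
            tree = random_mutation_tree(n, rng)
            col = rng.choice([0, 1, -1], size=n)
            got = marginal_singlet_likelihood(col, tree, THETA)
            assert got == pytest.approx(brute_singlet(col, tree, THETA),
                                        abs=1e-12)


class TestDoubletMixture:
    def test_delta_zero_collapses_to_singlet(self, caterpillar3, rng):
        theta0 = ErrorModel(alpha=0.01, beta=0.2, delta=0.0)
        col = rng.choice([0, 1, -1], size=3)
        assert doublet_mixture_likelihood(col, caterpillar3, theta0) == \
            pytest.approx(marginal_singlet_likelihood(col, caterpillar3, theta0))

    def test_matches_pair_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 4))
            tree = random_mutation_tree(n, rng)
            theta = ErrorModel(alpha=0.05, beta=0.3, delta=0.4)
            col = rng.choice([0, 1, -1], size=n)
            expect = 0.6 * brute_singlet(col, tree, theta) + \
                0.4 * brute_doublet(col, tree, theta)
            assert doublet_mixture_likelihood(col, tree, theta) == \
                pytest.approx(expect, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(2, 5), st.integers(0, 10**6))
def test_fast_doublet_equals_bruteforce_property(n, seed):
    """The O(n^2) LCA-based doublet sum equals full pair enumeration."""
    rng = np.random.default_rng(seed)
    tree = random_mutation_tree(n, rng)
    theta = ErrorModel(alpha=0.02, beta=0.25, delta=0.15)
    col = rng.choice([0, 1, -1], size=n)
    expect = 0.85 * brute_singlet(col, tree, theta) + \
        0.15 * brute_doublet(col, tree, theta)
    assert doublet_mixture_likelihood(col, tree, theta) == \
        pytest.approx(expect, abs=1e-12)


class TestScoreSc:
    def test_all_na_matrix_scores_zero(self, chain3, star3):
        D = SingleCellMatrix(np.full((3, 4), -1))
        for tree in (chain3, star3):
            s, _ = score_sc(D, tree, THETA, doublets=True)
            assert s == pytest.approx(0.0, abs=1e-12)

    def test_single_cell_single_mutation(self):
        D = SingleCellMatrix(np.array([[1]]))
        s, d = score_sc(D, MutationTree((2,)), THETA, doublets=False)
        assert s == pytest.approx(np.log(0.405))
        assert d == 0.0

    def test_empty_matrix_rejected(self, chain3):
        with pytest.raises(ValueError):
            score_sc(SingleCellMatrix(np.zeros((3, 0), dtype=np.int8)),
                     chain3, THETA)

    def test_column_permutation_invariance(self, rng):
        n, m = 4, 8
        tree = random_mutation_tree(n, rng)
        data = rng.choice([0, 1, -1], size=(n, m))
        s1, _ = score_sc(SingleCellMatrix(data), tree, THETA, doublets=True)
        s2, _ = score_sc(SingleCellMatrix(data[:, ::-1]), tree, THETA,
                         doublets=True)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_per_cell_likelihood_bounded(self, rng):
        n, m = 5, 6
        tree = random_mutation_tree(n, rng)
        D = SingleCellMatrix(rng.choice([0, 1, -1], size=(n, m)))
        s, _ = score_sc(D, tree, THETA, doublets=True)
        assert s <= 0.0

    def test_delta_maximisation_beats_brute_grid(self, rng):
        n, m = 3, 6
        tree = random_mutation_tree(n, rng)
        theta = ErrorModel(alpha=0.01, beta=0.2)
        D = SingleCellMatrix(rng.choice([0, 1, -1], size=(n, m)))
        s, delta_hat = score_sc(D, tree, theta, doublets=True)
        oracle = brute_sc_score(D, tree, theta,
                                delta_grid=np.linspace(0, 0.999, 2001))
        assert s >= oracle - 1e-6
        assert 0.0 <= delta_hat < 1.0

    def test_generating_tree_locally_optimal_on_clean_data(self):
        cfg = SimulationConfig(s=5, n=5, m=40, lambda_=1e4, alpha=0.0,
                               beta=0.0, na_rate=0.0, doublet_rate=0.0,
                               seed=11)
        rng = np.random.default_rng(11)
        truth = simulate_ground_truth(cfg, rng)
        G, _ = sample_cells(truth, cfg.m, cfg.lambda_, rng)
        D = SingleCellMatrix(G)
        tree = mutation_tree_from_singleton_clonal(truth.tree)
        theta = ErrorModel(alpha=1e-6, beta=1e-6)
        s_true, _ = score_sc(D, tree, theta, doublets=False)
        for v in range(1, 6):
            for p in range(1, 7):
                if p == v or p == tree.parent[v - 1] or p in tree.subtree(v):
                    continue
                s_alt, _ = score_sc(D, tree.with_parent(v, p), theta,
                                    doublets=False)
                assert s_alt <= s_true + 1e-9

    def test_posterior_concentrates_on_true_attachment(self):
        cfg = SimulationConfig(s=4, n=4, m=12, lambda_=1e4, alpha=0.0,
                               beta=0.0, na_rate=0.0, doublet_rate=0.0, seed=3)
        rng = np.random.default_rng(3)
        truth = simulate_ground_truth(cfg, rng)
        G, origins = sample_cells(truth, cfg.m, cfg.lambda_, rng)
        tree = mutation_tree_from_singleton_clonal(truth.tree)
        post = attachment_posterior(SingleCellMatrix(G), tree,
                                    ErrorModel(alpha=1e-9, beta=1e-9))
        # each cell's MAP attachment carries the same genotype as its origin
        A = np.asarray(
            __import__("jointphy").build_ancestor_matrix(tree))
        for j, clone in enumerate(origins):
            map_node = int(np.argmax(post[j])) + 1
            got = A[:, map_node - 1] if map_node <= 4 else np.zeros(4, int)
            assert np.array_equal(got, G[:, j])
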