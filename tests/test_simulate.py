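import numpy as np
import pytest

from jointphy import (SimulationConfig, apply_cna_shift, build_ancestor_matrix,
                      corrupt_genotypes, sample_cells, simulate_bulk,
                      simulate_dataset, simulate_ground_truth)
from jointphy.singlecell import NA


def cfg(**kw):
    base = dict(s=4, n=10, m=20, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGroundTruth:
    def test_s_equals_n_gives_mutation_tree(self, rng):
        truth = simulate_ground_truth(cfg(s=6, n=6), rng)
        assert all(len(lab) == 1 for lab in truth.tree.labels)

    def test_benchmark_shape_labels_cover_all(self, rng):
        truth = simulate_ground_truth(cfg(s=10, n=50), rng)
        sizes = [len(lab) for lab in truth.tree.labels]
        assert sum(sizes) == 50 and min(sizes) >= 1
        assert truth.tree.mutations == set(range(1, 51))

    def test_seed_reproducibility(self):
        c = cfg(seed=7)
        t1 = simulate_ground_truth(c)
        t2 = simulate_ground_truth(c)
        assert t1.tree.parent == t2.tree.parent
        assert t1.tree.labels == t2.tree.labels
        assert np.array_equal(t1.y, t2.y)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(s=5, n=3)
        with pytest.raises(ValueError):
            SimulationConfig(beta=1.0)

    def test_true_fractions_obey_subtree_sums(self, rng):
        truth = simulate_ground_truth(cfg(s=5, n=12, h=2), rng)
        tree = truth.tree
        A = np.asarray(build_ancestor_matrix(tree.parent), dtype=float)
        for i in range(truth.n):
            c = truth.clone_of_mutation[i]
            expect = A[c - 1] @ tree.phi[:tree.s]
            assert truth.y[i] == pytest.approx(expect)


class TestSampleCells:
    def test_high_lambda_tracks_prevalence(self, rng):
        truth = simulate_ground_truth(cfg(s=5, n=5), rng)
        prev = truth.tree.phi[:5, 0]
        prev = prev / prev.sum()
        tv = []
        for _ in range(100):
            p = np.bincount(
                sample_cells(truth, 400, 1e6, rng)[1] - 1, minlength=5) / 400
            tv.append(0.5 * np.abs(p - prev).sum())
        assert np.mean(tv) < 0.08  # sampling noise only

    def test_low_lambda_distorts_sampling(self, rng):
        truth = simulate_ground_truth(cfg(s=5, n=5), rng)
        prev = truth.tree.phi[:5, 0]
        prev = prev / prev.sum()

        def mean_tv(lam):
            vals = []
            for _ in range(60):
                p = np.bincount(
                    sample_cells(truth, 400, lam, rng)[1] - 1,
                    minlength=5) / 400
                vals.append(0.5 * np.abs(p - prev).sum())
            return np.mean(vals)

        assert mean_tv(0.1) > mean_tv(100.0)

    def test_genotypes_are_root_paths(self, rng):
        truth = simulate_ground_truth(cfg(s=4, n=8), rng)
        G, origins = sample_cells(truth, 30, 100.0, rng)
        A = np.asarray(build_ancestor_matrix(truth.tree.parent))
        for j, c in enumerate(origins):
            muts = set()
            for a in np.where(A[:, c - 1])[0] + 1:
                muts |= truth.tree.labels[a - 1]
            expect = np.zeros(8, dtype=np.int8)
            expect[[m - 1 for m in muts]] = 1
            assert np.array_equal(G[:, j], expect)

    def test_clean_genotypes_perfect_phylogeny(self, rng):
        # no pair of rows contains all three of (0,1), (1,0), (1,1)
        truth = simulate_ground_truth(cfg(s=6, n=12), rng)
        G, _ = sample_cells(truth, 200, 10.0, rng)
        for a in range(12):
            for b in range(a + 1, 12):
                pats = {(x, y) for x, y in zip(G[a], G[b])}
                assert not {(0, 1), (1, 0), (1, 1)} <= pats


class TestCorruptGenotypes:
    def test_zero_rates_identity(self, rng):
        G = rng.integers(0, 2, size=(6, 10)).astype(np.int8)
        D = corrupt_genotypes(G, 0.0, 0.0, 0.0, 0.0, rng)
        assert np.array_equal(D.data, G)

    def test_beta_one_removes_all_true_ones(self, rng):
        G = np.ones((5, 20), dtype=np.int8)
        D = corrupt_genotypes(G, 0.0, 0.999999, 0.0, 0.0, rng)
        assert D.data.sum() == 0

    def test_empirical_rates_match_configured(self, rng):
        # 10^6 entries: FP/FN/NA frequencies within 3 standard errors
        G = np.zeros((1000, 1000), dtype=np.int8)
        G[:500] = 1
        alpha, beta, na = 0.01, 0.2, 0.05
        D = corrupt_genotypes(G, alpha, beta, na, 0.0, rng)
        n_true1 = 500 * 1000
        obs = D.data
        fn_rate = ((obs[:500] == 0).sum()) / ((obs[:500] != NA).sum())
        fp_rate = ((obs[500:] == 1).sum()) / ((obs[500:] != NA).sum())
        na_rate = (obs == NA).mean()
        for got, want, n in ((fn_rate, beta, n_true1 * (1 - na)),
                             (fp_rate, alpha, n_true1 * (1 - na)),
                             (na_rate, na, 2 * n_true1)):
            se = np.sqrt(want * (1 - want) / n)
            assert abs(got - want) < 3 * se + 1e-12

    def test_doublets_only_add_mutations(self, rng):
        truth = simulate_ground_truth(cfg(s=4, n=8), rng)
        G, _ = sample_cells(truth, 50, 100.0, rng)
        D = corrupt_genotypes(G, 0.0, 0.0, 0.0, 1.0, rng)
        assert np.all(D.data >= G)  # OR with a partner never clears a 1


class TestSimulateBulk:
    def test_clonal_mutation_mean_fraction(self, rng):
        truth = simulate_ground_truth(cfg(s=2, n=2), rng)
        truth.y[:] = 1.0  # force clonal
        zs = [simulate_bulk(truth, 10_000, rng).z.mean() for _ in range(200)]
        se = np.sqrt(0.5 * 0.5 / 10_000) * 2 / np.sqrt(200 * 2)
        assert abs(np.mean(zs) - 1.0) < 3 * se

    def test_zero_fraction_no_variant_reads(self, rng):
        truth = simulate_ground_truth(cfg(s=2, n=4), rng)
        truth.y[:] = 0.0
        counts = simulate_bulk(truth, 1000, rng)
        assert counts.r.sum() == 0

    def test_multisample_tracks_per_sample_fractions(self, rng):
        truth = simulate_ground_truth(cfg(s=3, n=6, h=2), rng)
        reps = [simulate_bulk(truth, 10_000, rng).z for _ in range(100)]
        zbar = np.mean(reps, axis=0)
        assert zbar == pytest.approx(truth.y, abs=0.01)


class TestCnaShift:
    def test_zero_count_unchanged(self, rng):
        truth = simulate_ground_truth(cfg(), rng)
        counts = simulate_bulk(truth, 1000, rng)
        shifted = apply_cna_shift(counts, truth, 0, rng)
        assert np.array_equal(shifted.r, counts.r)

    def test_perturbed_set_recorded(self, rng):
        truth = simulate_ground_truth(cfg(), rng)
        counts = simulate_bulk(truth, 1000, rng)
        apply_cna_shift(counts, truth, 3, rng)
        assert len(truth.cna_events) == 3
        assert all(f in (0.5, 1.5) for _, f in truth.cna_events)

    def test_amplified_clonal_mutation_exceeds_one(self, rng):
        truth = simulate_ground_truth(cfg(s=2, n=2), rng)
        truth.y[:] = 1.0
        counts = simulate_bulk(truth, 10_000, rng)
        # factor 1.5 on a clonal mutation (y = 1) gives success prob 0.75,
        # hence expected observed fraction z = 1.5 (above 1)
        rng2 = np.random.default_rng(0)
        while not truth.cna_events or truth.cna_events[0][1] != 1.5:
            truth.cna_events.clear()
            shifted = apply_cna_shift(counts, truth, 1, rng2)
        i = truth.cna_events[0][0]
        assert shifted.z[i - 1, 0] == pytest.approx(1.5, abs=0.05)


def test_dataset_end_to_end_shapes():
    c = cfg(s=6, n=20, m=25, h=2, cna_count=2)
    truth, D, counts = simulate_dataset(c)
    assert D.n == 20 and D.m == 25
    assert counts.n == 20 and counts.h == 2
    assert len(truth.cna_events) == 2
    t2 = simulate_dataset(c)
    assert np.array_equal(t2[1].data, D.data)
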