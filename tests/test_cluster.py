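import itertools

import numpy as np
import pytest

from sibpop.cluster import (
    ClusterConfig,
    MembershipMatrix,
    align_replicates,
    fit_admixture,
    fit_replicates,
    k_diagnostics,
    pairwise_g,
)
from sibpop.genio import MISSING, GenotypeTable
from conftest import random_table


class TestFitAdmixture:
    def test_k1_degenerate(self, two_deme_dataset):
        table = two_deme_dataset.genotypes
        res = fit_admixture(table, ClusterConfig(K=1, seed=0))
        assert np.array_equal(res.Q, np.ones((table.n, 1)))
        # cluster frequencies equal observed frequencies
        col = table.calls[:, 0, :]
        flat = col[col != MISSING]
        codes, counts = np.unique(flat, return_counts=True)
        np.testing.assert_allclose(res.freqs[0][0], counts / counts.sum())

    def test_fixed_differences_assign_confidently(self):
        """Two demes with fixed allelic differences at 10 loci: every individual's
        membership in its true deme is >= 0.95 (up to label swap)."""
        n = 15
        calls = np.empty((2 * n, 10, 2), dtype=int)
        calls[:n] = 1
        calls[n:] = 2
        table = GenotypeTable([f"i{k}" for k in range(2 * n)], [f"L{j}" for j in range(10)], calls)
        reps = fit_replicates(table, ClusterConfig(K=2, replicates=3, seed=1))
        q = align_replicates(reps, seed=1).Q_mean.Q
        col0 = 0 if q[:n, 0].mean() > 0.5 else 1
        assert q[:n, col0].min() >= 0.95
        assert q[n:, 1 - col0].min() >= 0.95

    def test_two_simulated_demes_separate(self, two_deme_dataset):
        ds = two_deme_dataset
        reps = fit_replicates(ds.genotypes, ClusterConfig(K=2, replicates=3, seed=1))
        q = align_replicates(reps, seed=1).Q_mean.Q
        truth = ds.truth["deme"].to_numpy()
        col0 = 0 if q[truth == 0, 0].mean() > 0.5 else 1
        assert q[truth == 0, col0].mean() > 0.85
        assert q[truth == 1, 1 - col0].mean() > 0.85

    def test_label_permutation_leaves_likelihood_unchanged(self, two_deme_dataset):
        table = two_deme_dataset.genotypes
        cfg = ClusterConfig(K=2, seed=3)
        res = fit_admixture(table, cfg)
        # recompute likelihood with swapped labels
        idx_cols = [1, 0]
        loglik = 0.0
        for j in range(table.n_loci):
            p = res.freqs[j][idx_cols, :]
            codes = res.allele_codes[j]
            lookup = {c: i for i, c in enumerate(codes)}
            for i in range(table.n):
                for c in (0, 1):
                    a = table.calls[i, j, c]
                    if a == MISSING:
                        continue
                    loglik += np.log(res.Q[i, idx_cols] @ p[:, lookup[a]])
        assert loglik == pytest.approx(res.loglik, rel=1e-9)

    def test_rows_sum_to_one(self, two_deme_dataset):
        res = fit_admixture(two_deme_dataset.genotypes, ClusterConfig(K=3, seed=4))
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)

    def test_k_exceeding_n_rejected(self):
        t = random_table(np.random.default_rng(0), n=3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(t, ClusterConfig(K=5))

    def test_panmictic_memberships_near_half(self, panmictic_dataset):
        """Without real structure the aligned mean memberships stay near 0.5."""
        reps = fit_replicates(panmictic_dataset.genotypes, ClusterConfig(K=2, replicates=10, seed=5))
        q = align_replicates(reps, seed=5).Q_mean.Q
        assert np.abs(q[:, 0] - 0.5).mean() < 0.2
        assert np.abs(q[:, 0] - 0.5).max() < 0.45


class TestAlignment:
    def test_identical_replicates(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(3), size=10)
        reps = [MembershipMatrix(q.copy(), 0.0, [str(i) for i in range(10)]) for _ in range(4)]
        res = align_replicates(reps)
        assert res.G == pytest.approx(1.0)
        assert all(p == (0, 1, 2) for p in res.permutations)

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(1)
        q = rng.dirichlet(np.ones(2), size=10)
        ids = [str(i) for i in range(10)]
        reps = [MembershipMatrix(q, 0.0, ids), MembershipMatrix(q[:, ::-1], 0.0, ids)]
        res = align_replicates(reps)
        assert res.G == pytest.approx(1.0)
        assert res.permutations[0] != res.permutations[1]
        np.testing.assert_allclose(res.Q_mean.Q, q)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_brute_force_optimum(self, k):
        """Greedy alignment with restarts equals exhaustive search over K! per replicate."""
        rng = np.random.default_rng(2)
        for trial in range(4):
            qs = [rng.dirichlet(np.ones(k), size=8) for _ in range(3)]
            reps = [MembershipMatrix(q, 0.0, [str(i) for i in range(8)]) for q in qs]
            got = align_replicates(reps, repeats=60, seed=trial).G
            best = -1.0
            perms = list(itertools.permutations(range(k)))
            for combo in itertools.product(perms, repeat=3):
                aligned = [q[:, p] for q, p in zip(qs, combo)]
                score = np.mean([pairwise_g(aligned[i], aligned[j]) for i in range(3) for j in range(i + 1, 3)])
                best = max(best, score)
            assert got == pytest.approx(best, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        a = MembershipMatrix(np.full((4, 2), 0.5), 0.0, list("abcd"))
        b = MembershipMatrix(np.full((5, 2), 0.5), 0.0, list("abcde"))
        with pytest.raises(ValueError, match="mismatch"):
            align_replicates([a, b])


class TestKDiagnostics:
    def test_hand_evaluated_delta_k(self):
        """Evanno delta-K on means (-100, -50, -40, -38) with sd 1 gives 40 and 8."""
        # two replicates symmetric about the mean with ddof=1 sd exactly 1
        half = np.sqrt(0.5)
        obj = {k: [m - half, m + half] for k, m in [(1, -100.0), (2, -50.0), (3, -40.0), (4, -38.0)]}
        diag = k_diagnostics(obj).set_index("K")
        assert diag.loc[2, "delta_k"] == pytest.approx(40.0)
        assert diag.loc[3, "delta_k"] == pytest.approx(8.0)
        assert np.isnan(diag.loc[1, "delta_k"]) and np.isnan(diag.loc[4, "delta_k"])

    def test_flat_objective_gives_zero(self):
        obj = {k: [-10.0 + d for d in (-1, 1)] for k in (1, 2, 3)}
        diag = k_diagnostics(obj).set_index("K")
        assert diag.loc[2, "delta_k"] == pytest.approx(0.0)

    def test_scale_invariance_of_ratio(self):
        rng = np.random.default_rng(3)
        obj = {k: list(rng.normal(-50.0 * k, 3.0, size=5)) for k in range(1, 6)}
        scaled = {k: [3.0 * v for v in vals] for k, vals in obj.items()}
        d1 = k_diagnostics(obj)["delta_k"].to_numpy()
        d2 = k_diagnostics(scaled)["delta_k"].to_numpy()
        np.testing.assert_allclose(d1, d2, rtol=1e-10)

    def test_zero_sd_flagged(self):
        obj = {1: [-5.0, -5.0], 2: [-4.0, -4.0], 3: [-3.0, -3.0]}
        diag = k_diagnostics(obj).set_index("K")
        assert np.isnan(diag.loc[2, "delta_k"])
        assert "sd=0" in diag.loc[2, "flag"]
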