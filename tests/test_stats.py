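import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform


from sibpop import stats as st
from sibpop.genio import GenotypeTable
from conftest import random_table
from _oracles import jost_d_oracle, wc_theta_oracle


def table_from_groups(group_calls):
    ids, labels, rows = [], {}, []
    for gi, calls in enumerate(group_calls):
        members = []
        for i in range(len(calls)):
            ind = f"g{gi}_{i}"
            ids.append(ind)
            members.append(ind)
            rows.append(calls[i])
        labels[f"G{gi}"] = members
    loci = [f"L{j}" for j in range(group_calls[0].shape[1])]
    return GenotypeTable(ids, loci, np.array(rows)), labels


class TestAlleleFreqs:
    def test_simple_counts(self):
        t = GenotypeTable(["a", "b"], ["L1"], np.array([[[1, 1]], [[1, 2]]]))
        f = st.allele_freqs(t)["L1"]
        assert f[1] == pytest.approx(0.75) and f[2] == pytest.approx(0.25)

    def test_all_missing_locus_flagged_empty(self):
        t = GenotypeTable(["a", "b"], ["L1"], np.zeros((2, 1, 2), dtype=int))
        assert st.allele_freqs(t)["L1"].empty

    def test_frequencies_normalized(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            t = random_table(np.random.default_rng(seed), n=10, loci=4, missing_rate=0.3)
            for f in st.allele_freqs(t).values():
                if not f.empty:
                    assert f.sum() == pytest.approx(1.0, abs=1e-12)


class TestDiversity:
    @pytest.mark.parametrize(
        "ho,he,expected",
        [(0.782, 0.845, 0.075), (0.802, 0.843, 0.049), (0.787, 0.818, 0.038), (0.657, 0.712, 0.077), (0.778, 0.801, 0.029)],
    )
    def test_fis_from_published_heterozygosities(self, ho, he, expected):
        assert round(st.fis(ho, he), 3) == expected

    def test_equifrequent_alleles_closed_form(self):
        # 4 alleles, each at frequency 1/4
        k, m = 4, 40
        a1 = np.arange(m) % k + 1
        a2 = np.roll(a1, 1)
        t = GenotypeTable([f"i{i}" for i in range(m)], ["L1"], np.column_stack([a1, a2]).reshape(m, 1, 2))
        row = st.diversity_summary(t).iloc[0]
        assert row["Ae"] == pytest.approx(k)
        assert row["He"] == pytest.approx(1 - 1 / k)
        assert row["A95"] == k
        assert row["A"] == k

    def test_fis_undefined_when_monomorphic(self):
        t = GenotypeTable(["a", "b"], ["L1"], np.ones((2, 1, 2), dtype=int))
        row = st.diversity_summary(t).iloc[0]
        assert np.isnan(row["FIS"]) and row["He"] == 0.0


class TestThetaAndJost:
    def fixed_tables(self):
        n = 8
        a = np.full((n, 5, 2), 1)
        b = np.full((n, 5, 2), 2)
        return table_from_groups([a, b])

    def test_fixation_limits(self):
        t, groups = self.fixed_tables()
        assert st.theta_st(t, groups)[0] == pytest.approx(1.0)
        assert st.jost_d(t, groups)[0] == pytest.approx(1.0)

    def test_identical_groups(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 5, size=(10, 4, 2))
        t, groups = table_from_groups([base, base.copy()])
        assert st.theta_st(t, groups)[0] <= 0.0
        assert st.jost_d(t, groups)[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracles(self, seed):
        """Vectorized estimators agree with scalar-loop formula oracles to 1e-10."""
        rng = np.random.default_rng(seed)
        gcalls = [rng.integers(1, 4, size=(6, 2, 2)) for _ in range(2)]
        t, groups = table_from_groups(gcalls)
        assert st.theta_st(t, groups)[0] == pytest.approx(wc_theta_oracle(gcalls), abs=1e-10)
        assert st.jost_d(t, groups)[0] == pytest.approx(jost_d_oracle(gcalls), abs=1e-10)

    def test_theta_monotone_in_drift(self):
        """Weir-Cockerham theta tracks the simulated drift parameter F."""
        from sibpop.simulate import SimConfig, balanced_tree, simulate_hierarchical

        thetas = []
        for f in (0.02, 0.05, 0.1, 0.2, 0.4):
            ds = simulate_hierarchical(SimConfig(tree=balanced_tree(1), F=f, samples_per_deme=40, loci=15, seed=3))
            groups = {"0": [i for i, d in ds.truth["deme"].items() if d == 0], "1": [i for i, d in ds.truth["deme"].items() if d == 1]}
            thetas.append(st.theta_st(ds.genotypes, groups)[0])
        assert all(b > a for a, b in zip(thetas, thetas[1:]))


class TestEquilibriumTests:
    def test_extreme_heterozygote_excess_detected(self):
        calls = np.tile([1, 2], (20, 1)).reshape(20, 1, 2)
        t = GenotypeTable([f"i{i}" for i in range(20)], ["L1"], calls)
        assert st.hwp_test(t, None, "L1", reps=9999, seed=1) < 0.05

    def test_monomorphic_locus_skipped(self):
        t = GenotypeTable(["a", "b", "c"], ["L1"], np.ones((3, 1, 2), dtype=int))
        assert np.isnan(st.hwp_test(t, None, "L1"))
        t2 = GenotypeTable(
            ["a", "b", "c"], ["L1", "L2"],
            np.concatenate([np.ones((3, 1, 2), dtype=int), np.array([[[1, 2]], [[2, 2]], [[1, 1]]])], axis=1),
        )
        assert np.isnan(st.ld_test(t2, None, ("L1", "L2")))

    def test_duplicated_locus_in_strong_disequilibrium(self):
        rng = np.random.default_rng(2)
        l1 = rng.integers(1, 4, (30, 1, 2))
        t = GenotypeTable([f"i{i}" for i in range(30)], ["L1", "L2"], np.concatenate([l1, l1], axis=1))
        assert st.ld_test(t, None, ("L1", "L2"), reps=9999, seed=3) < 0.05

    def test_permutation_p_never_zero(self):
        calls = np.tile([1, 2], (10, 1)).reshape(10, 1, 2)
        t = GenotypeTable([f"i{i}" for i in range(10)], ["L1"], calls)
        assert st.hwp_test(t, None, "L1", reps=99, seed=0) >= 1 / 100

    def test_bonferroni(self):
        p = np.array([0.01, 0.04, np.nan])
        np.testing.assert_allclose(st.bonferroni(p)[:2], [0.02, 0.08])


class TestAmovaDistance:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [((1, 1), (1, 1), 0), ((1, 1), (2, 2), 4), ((1, 2), (1, 3), 1), ((1, 2), (3, 4), 2), ((1, 1), (2, 3), 3), ((1, 1), (1, 2), 1), ((1, 2), (1, 2), 0)],
    )
    def test_codominant_distance_table(self, g1, g2, expected):
        t = GenotypeTable(["a", "b"], ["L1"], np.array([[g1], [g2]]))
        assert st.amova_distance(t)[0, 1] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self):
        t = random_table(np.random.default_rng(5), n=12, loci=4, missing_rate=0.2)
        d = st.amova_distance(t)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_missing_loci_rescaled(self):
        # identical at typed locus, one locus missing for b -> distance from the
        # shared locus scaled up by 2/1
        calls = np.array([[[1, 2], [3, 3]], [[1, 2], [0, 0]], [[3, 4], [3, 3]]])
        t = GenotypeTable(["a", "b", "c"], ["L1", "L2"], calls)
        d = st.amova_distance(t)
        assert d[0, 1] == pytest.approx(0.0)
        assert d[1, 2] == pytest.approx(2 * 2.0)  # one shared locus, (1,2)v(3,4)=2, rescaled x2

    def test_no_overlap_raises(self):
        calls = np.array([[[1, 1], [0, 0]], [[0, 0], [2, 2]]])
        t = GenotypeTable(["a", "b"], ["L1", "L2"], calls)
        with pytest.raises(ValueError, match="shared"):
            st.amova_distance(t)


class TestMantelCorrelog:
    def ibd_matrices(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (n, 2))
        geo = squareform(pdist(pts))
        gen = 2.0 * geo / geo.max() + rng.normal(0, 0.01, geo.shape)
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        return geo, gen

    def test_monotone_genetic_distance_sign_pattern(self):
        geo, gen = self.ibd_matrices()
        res = st.mantel_correlog(geo, gen, n_classes=8, reps=499, seed=1).table
        tested = res[res["tested"]]
        first, last = tested.iloc[0], tested.iloc[-1]
        assert first["r"] > 0 and first["p_corr"] <= 0.05
        assert last["r"] < 0

    def test_progressive_correction_definition(self):
        geo, gen = self.ibd_matrices(seed=3)
        res = st.mantel_correlog(geo, gen, n_classes=6, reps=99, seed=2).table
        tested = res[res["tested"]].reset_index()
        for k, row in tested.iterrows():
            assert row["p_corr"] == pytest.approx(min(1.0, row["p_raw"] * (k + 1)))
            assert row["p_corr"] >= row["p_raw"]

    def test_class_bounds_ascending_nonoverlapping(self):
        geo, gen = self.ibd_matrices(seed=4)
        res = st.mantel_correlog(geo, gen, n_classes=10, reps=49, seed=0).table
        assert (res["hi_km"].to_numpy() > res["lo_km"].to_numpy()).all()
        assert (res["lo_km"].to_numpy()[1:] == res["hi_km"].to_numpy()[:-1]).all()

    def test_asymmetric_matrix_rejected(self):
        geo, gen = self.ibd_matrices(seed=5)
        gen[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            st.mantel_correlog(geo, gen)

    def test_matches_vegan_mantel_statistic(self, tmp_path):
        """Per-class Mantel r agrees with vegan's mantel() on the indicator matrix."""
        geo, gen = self.ibd_matrices(n=14, seed=6)
        res = st.mantel_correlog(geo, gen, n_classes=4, reps=49, seed=0)
        edges = res.breaks
        np.savetxt(tmp_path / "gen.txt", gen)
        np.savetxt(tmp_path / "geo.txt", geo)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            gen <- as.matrix(read.table('{tmp_path}/gen.txt'))
            geo <- as.matrix(read.table('{tmp_path}/geo.txt'))
            edges <- c({','.join(str(e) for e in edges)})
            for (k in 1:4) {{
              ind <- (geo > edges[k] | (k == 1 & geo <= edges[2])) & geo <= edges[k+1]
              mode(ind) <- 'numeric'; diag(ind) <- 0
              r <- suppressWarnings(mantel(as.dist(ind), as.dist(gen), permutations=0))$statistic
              cat(-r, '\\n')
            }}
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        vegan_r = np.array([float(x) for x in out.stdout.split()])
        ours = res.table["r"].to_numpy()
        mask = ~np.isnan(ours)
        assert mask.sum() >= 2
        np.testing.assert_allclose(ours[mask], vegan_r[mask], atol=1e-6)
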