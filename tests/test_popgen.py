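import numpy as np
import pandas as pd
import pytest

from nestkin import popgen as pg
from nestkin import simulate as sim
from nestkin.io import table_from_records


def table_of(genos_by_colony, loci=("L1",)):
    recs = []
    for colony, genos in genos_by_colony.items():
        for i, g in enumerate(genos):
            geno = g if isinstance(g, dict) else {loci[0]: g}
            recs.append({"id": f"{colony}{i}", "colony": colony, "caste": "worker",
                         "ploidy": 2, "genotype": geno})
    return table_from_records(recs, loci)


def hw_population_table(n_colonies, per_colony, panel, rng):
    """Individuals drawn at exact Hardy-Weinberg proportions (no family structure)."""
    recs = []
    for c in range(n_colonies):
        for i in range(per_colony):
            geno = {
                s.name: tuple(sorted(rng.choice(s.alleles, 2, p=s.frequencies)))
                for s in panel
            }
            recs.append({"id": f"c{c}i{i}", "colony": f"c{c}", "caste": "worker",
                         "ploidy": 2, "genotype": geno})
    return table_from_records(recs, [s.name for s in panel])


class TestLocusSummaries:
    def test_all_homozygous(self):
        t = table_of({"A": [(1, 1), (2, 2), (1, 1)]})
        summaries, overall = pg.locus_summaries(t)
        assert summaries[0].h_obs == 0.0
        assert overall["h_obs"] == 0.0

    def test_h_obs_plus_homozygotes_is_one(self):
        t = table_of({"A": [(1, 1), (1, 2), (2, 2), (1, 2)]})
        s = pg.locus_summaries(t)[0][0]
        hom = 2 / 4
        assert s.h_obs + hom == pytest.approx(1.0)

    def test_nei_unbiased_formula(self):
        # 2 individuals, alleles 1,1,1,2: f = (3/4, 1/4); He = (4/3)(1-10/16)
        t = table_of({"A": [(1, 1), (1, 2)]})
        s = pg.locus_summaries(t)[0][0]
        assert s.h_exp == pytest.approx((4 / 3) * (1 - (9 + 1) / 16))

    def test_relabeling_invariance(self):
        t1 = table_of({"A": [(1, 2), (1, 1), (2, 2)]})
        t2 = table_of({"A": [(7, 9), (7, 7), (9, 9)]})
        s1 = pg.locus_summaries(t1)[0][0]
        s2 = pg.locus_summaries(t2)[0][0]
        assert s1.h_exp == pytest.approx(s2.h_exp)
        assert s1.h_obs == pytest.approx(s2.h_obs)


class TestHWEExact:
    def test_all_heterozygotes_extreme(self):
        genos = [(1, 2)] * 50
        p = pg.hwe_exact(genos)
        assert p is not None and p < 0.001

    def test_monomorphic_not_applicable(self):
        assert pg.hwe_exact([(1, 1)] * 10) is None

    def test_biallelic_matches_shuffle_simulation(self):
        # independent oracle: empirical conditional distribution by shuffling
        rng = np.random.default_rng(61)
        genos = [(1, 1)] * 3 + [(1, 2)] * 2 + [(2, 2)] * 4
        p_exact = pg.hwe_exact(genos)
        pool = np.array([a for g in genos for a in g])
        n_het_obs = sum(g[0] != g[1] for g in genos)

        def prob_weight(h):  # relative conditional probability of h heterozygotes
            import math

            n_a = int((pool == 1).sum())
            n_b = int((pool == 2).sum())
            return (
                2**h
                / (math.factorial((n_a - h) // 2) * math.factorial(h)
                   * math.factorial((n_b - h) // 2))
            )

        hets = []
        for _ in range(20000):
            rng.shuffle(pool)
            pairs = pool.reshape(-1, 2)
            hets.append(int((pairs[:, 0] != pairs[:, 1]).sum()))
        hets = np.array(hets)
        w_obs = prob_weight(n_het_obs)
        p_sim = np.mean([prob_weight(h) <= w_obs * (1 + 1e-12) for h in hets])
        assert p_exact == pytest.approx(p_sim, abs=0.02)

    def test_resampled_requires_colonies(self, panel7):
        t = table_of({"A": [(1, 2), (1, 1)]})
        with pytest.raises(ValueError, match="colonies"):
            pg.hwe_exact_resampled(t, n_replicates=2, seed=0)

    def test_type_one_error_calibrated(self, panel7):
        rng = np.random.default_rng(62)
        t = hw_population_table(40, 5, panel7, rng)
        df, summary = pg.hwe_exact_resampled(t, n_replicates=4, seed=63, n_mc=2000)
        # 28 null tests at alpha 0.05: significant count within 99% binomial bounds
        from scipy.stats import binom

        upper = binom.ppf(0.995, summary["n_tests"], 0.05)
        assert summary["n_significant"] <= upper


class TestLD:
    def test_duplicated_locus_perfect_association(self):
        rng = np.random.default_rng(64)
        recs = []
        for c in range(20):
            a = tuple(sorted(rng.integers(1, 5, 2)))
            recs.append({"id": f"i{c}", "colony": f"c{c}", "caste": "worker",
                         "ploidy": 2, "genotype": {"L1": a, "L2": a}})
        t = table_from_records(recs, ["L1", "L2"])
        df, _ = pg.ld_test_resampled(t, n_replicates=1, n_perms=200, seed=65)
        assert df["p"].iloc[0] <= 3 / 201

    def test_independent_loci_calibrated(self, panel7):
        rng = np.random.default_rng(66)
        t = hw_population_table(30, 1, panel7[:4], rng)
        df, summary = pg.ld_test_resampled(t, n_replicates=3, n_perms=200,
                                           alpha=0.05, seed=67)
        from scipy.stats import binom

        upper = binom.ppf(0.995, summary["n_tests"], 0.05)
        assert summary["n_significant"] <= upper

    def test_monomorphic_pair_not_applicable(self):
        t = table_of(
            {"A": [{"L1": (1, 1), "L2": (1, 2)}], "B": [{"L1": (1, 1), "L2": (2, 2)}]},
            loci=("L1", "L2"),
        )
        df, _ = pg.ld_test_resampled(t, n_replicates=1, n_perms=50, seed=68)
        assert df["p"].isna().all()


class TestWeirCockerham:
    def test_fixed_demes_theta_one(self):
        t = table_of({"A": [(1, 1)] * 5, "B": [(2, 2)] * 5})
        r = pg.weir_cockerham_fstats(t, n_bootstrap=10, seed=0)
        assert r.f_st == pytest.approx(1.0)

    def test_panmictic_split_theta_near_zero(self, panel7):
        rng = np.random.default_rng(71)
        recs = []
        for i in range(200):
            geno = {
                s.name: tuple(sorted(rng.choice(s.alleles, 2, p=s.frequencies)))
                for s in panel7
            }
            recs.append({"id": f"i{i}", "colony": "A" if i < 100 else "B",
                         "caste": "worker", "ploidy": 2, "genotype": geno})
        t = table_from_records(recs, [s.name for s in panel7])
        r = pg.weir_cockerham_fstats(t, n_bootstrap=100, seed=1)
        assert abs(r.f_st) < 0.02

    def test_hand_computed_fixture(self):
        # deme A: 1/1, 1/1, 1/2, 2/2; deme B: 1/2, 1/2, 2/2
        # exact variance components give theta = -49/1819, f_is = 107/467
        t = table_of({"A": [(1, 1), (1, 1), (1, 2), (2, 2)],
                      "B": [(1, 2), (1, 2), (2, 2)]})
        r = pg.weir_cockerham_fstats(t, n_bootstrap=10, seed=0)
        assert r.f_st == pytest.approx(-49 / 1819, abs=1e-12)
        assert r.f_is == pytest.approx(107 / 467, abs=1e-12)

    def test_allele_code_permutation_invariance(self):
        t1 = table_of({"A": [(1, 1), (1, 2)], "B": [(2, 2), (1, 2)]})
        t2 = table_of({"A": [(9, 9), (3, 9)], "B": [(3, 3), (3, 9)]})
        r1 = pg.weir_cockerham_fstats(t1, n_bootstrap=10, seed=0)
        r2 = pg.weir_cockerham_fstats(t2, n_bootstrap=10, seed=0)
        assert r1.f_st == pytest.approx(r2.f_st)

    def test_single_deme_rejected(self):
        t = table_of({"A": [(1, 2), (1, 1)]})
        with pytest.raises(ValueError, match="single deme"):
            pg.weir_cockerham_fstats(t)

    def test_fis_negative_on_family_structured_colonies(self, panel7):
        rng = np.random.default_rng(72)
        colonies = [
            sim.simulate_colony(panel7, sim.ColonySpec(10, (6, 4)), seed=rng,
                                colony_id=f"N{i:02d}")
            for i in range(15)
        ]
        t = sim.combine_colonies(colonies).of_caste("worker")
        r = pg.weir_cockerham_fstats(t, n_bootstrap=100, seed=2)
        assert r.f_is < 0  # sib groups carry an excess of heterozygotes
        assert r.f_st > 0

    def test_multilocus_theta_within_per_locus_range(self, panel7):
        rng = np.random.default_rng(73)
        colonies = [
            sim.simulate_colony(panel7, sim.ColonySpec(8, (8,)), seed=rng,
                                colony_id=f"N{i:02d}")
            for i in range(10)
        ]
        t = sim.combine_colonies(colonies).of_caste("worker")
        r = pg.weir_cockerham_fstats(t, n_bootstrap=10, seed=3)
        per_locus = r.per_locus
        thetas = per_locus["a"] / (per_locus["a"] + per_locus["b"] + per_locus["c"])
        assert thetas.min() - 1e-9 <= r.f_st <= thetas.max() + 1e-9


class TestPairwiseFst:
    def test_identical_colonies_zero(self):
        t = table_of({"A": [(1, 2)] * 4, "B": [(1, 2)] * 4})
        m = pg.pairwise_fst(t)
        assert m.loc["A", "B"] == pytest.approx(0.0)

    def test_fixed_different_one(self):
        t = table_of({"A": [(1, 1)] * 4, "B": [(2, 2)] * 4})
        m = pg.pairwise_fst(t)
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetry_and_diagonal(self, panel7):
        rng = np.random.default_rng(74)
        colonies = [
            sim.simulate_colony(panel7, sim.ColonySpec(6, (6,)), seed=rng,
                                colony_id=f"N{i}")
            for i in range(4)
        ]
        t = sim.combine_colonies(colonies).of_caste("worker")
        m = pg.pairwise_fst(t)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(m.to_numpy()), 0)


class TestGTestDifferentiation:
    def test_split_colony_not_significant(self, panel7):
        rng = np.random.default_rng(75)
        col = sim.simulate_colony(panel7, sim.ColonySpec(16, (8, 8)), seed=rng)
        t = col.table.of_caste("worker")
        data = t.data.copy()
        data.loc[data.index[:8], "colony"] = "half1"
        data.loc[data.index[8:], "colony"] = "half2"
        from nestkin.io import GenotypeTable

        t2 = GenotypeTable(data.reset_index(drop=True), t.loci)
        df = pg.gtest_pairwise_differentiation(t2, n_perms=500, seed=76)
        assert not df["significant"].iloc[0]

    def test_unrelated_colonies_significant(self, panel7):
        rng = np.random.default_rng(77)
        colonies = [
            sim.simulate_colony(panel7, sim.ColonySpec(12, (6, 6)), seed=rng,
                                colony_id=f"N{i}")
            for i in range(2)
        ]
        t = sim.combine_colonies(colonies)
        df = pg.gtest_pairwise_differentiation(t, n_perms=2000, seed=78)
        assert df["significant"].iloc[0]

    def test_fisher_combination_of_ones(self):
        import math

        from scipy.stats import chi2

        x = -2 * sum(math.log(1.0) for _ in range(3))
        assert chi2.sf(x, 6) == pytest.approx(1.0)


class TestEvannoDeltaK:
    def test_quadratic_with_run_offsets_flat(self):
        ks = range(1, 7)
        rows = []
        for offset in (0.0, 5.0, -3.0):
            rows.append({k: -(k - 3.5) ** 2 * 10 + offset for k in ks})
        lnp = pd.DataFrame(rows)
        df = pg.evanno_delta_k(lnp)
        vals = df.loc[df["defined"], "delta_k"].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_kink_at_two(self):
        ks = range(1, 6)
        rows = []
        rng = np.random.default_rng(79)
        for _ in range(5):
            noise = rng.normal(0, 0.5, len(list(ks)))
            base = {1: -500.0, 2: -300.0, 3: -295.0, 4: -292.0, 5: -290.0}
            rows.append({k: base[k] + noise[k - 1] for k in ks})
        df = pg.evanno_delta_k(pd.DataFrame(rows))
        assert df.attrs["best_k"] == 2

    def test_two_k_values_rejected(self):
        lnp = pd.DataFrame([{1: -10.0, 2: -5.0}, {1: -11.0, 2: -6.0}])
        with pytest.raises(ValueError, match="at least 3"):
            pg.evanno_delta_k(lnp)

    def test_zero_sd_flagged(self):
        lnp = pd.DataFrame([{1: -10.0, 2: -5.0, 3: -2.0}] * 3)
        df = pg.evanno_delta_k(lnp)
        assert not df["defined"].any()
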