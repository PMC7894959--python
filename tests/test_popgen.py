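"""SSR statistics against closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from endemica import popgen
from endemica.synth import SynthSpec, generate_genotypes

from conftest import make_table, pop_locus_genotypes, random_table
from oracles import (
    amova_oracle,
    diversity_oracle,
    genotype_distance_oracle,
    nei_fstats_oracle,
    nei_unbiased_distance_oracle,
)


class TestAlleleFrequencies:
    def test_simple_counting(self):
        g = make_table({"P": [[(100, 100)], [(100, 102)], [(102, 102)], [(0, 0)]]})
        af = popgen.allele_frequencies(g)
        assert af.n_typed[("P", "L1")] == 3
        assert af.freqs[("P", "L1")] == {100: 0.5, 102: 0.5}

    def test_pooled_weighted(self):
        g = make_table(
            {
                "A": [[(100, 100)]] * 3,          # 6 copies of 100
                "B": [[(102, 102)]],              # 2 copies of 102
            }
        )
        af = popgen.allele_frequencies(g)
        assert af.pooled("L1") == {100: pytest.approx(0.75), 102: pytest.approx(0.25)}
        assert af.alleles("L1") == [100, 102]


class TestDiversity:
    def test_closed_forms(self):
        # 4 typed: freqs 100 -> 5/8, 102 -> 3/8; 1 of 4 heterozygous
        g = make_table(
            {"P": [[(100, 100)], [(100, 100)], [(100, 102)], [(102, 102)]]}
        )
        row = popgen.diversity(g).per_locus.iloc[0]
        he = 1 - (5 / 8) ** 2 - (3 / 8) ** 2
        assert row["He"] == pytest.approx(he)
        assert row["uHe"] == pytest.approx(he * 8 / 7)
        assert row["Ho"] == pytest.approx(0.25)
        assert row["Ne"] == pytest.approx(1 / ((5 / 8) ** 2 + (3 / 8) ** 2))
        assert row["I"] == pytest.approx(
            -(5 / 8) * math.log(5 / 8) - (3 / 8) * math.log(3 / 8)
        )
        assert row["F"] == pytest.approx(1 - 0.25 / he)

    def test_monomorphic_f_excluded_from_means(self):
        g = make_table(
            {"P": [[(100, 100), (100, 102)], [(100, 100), (100, 102)]]}
        )
        summary = popgen.diversity(g).by_subpop.iloc[0]
        assert summary["P"] == pytest.approx(50.0)  # 1 of 2 loci polymorphic
        assert not math.isnan(summary["F"])  # mean over the polymorphic locus only
        assert summary["F"] == pytest.approx(1 - 1.0 / 0.5)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(10):
            g = random_table(rng)
            per_locus = popgen.diversity(g).per_locus
            for _, row in per_locus.iterrows():
                expected = diversity_oracle(
                    pop_locus_genotypes(g, row["subpopulation"], row["locus"])
                )
                for key in ("N", "Na", "Ne", "Ho", "He", "uHe", "I"):
                    assert row[key] == pytest.approx(expected[key], abs=1e-12)


class TestPic:
    def test_known_values(self):
        assert popgen.pic([0.5, 0.5]) == pytest.approx(0.375)
        assert popgen.pic([1 / 3] * 3) == pytest.approx(16 / 27)
        assert popgen.pic({100: 1.0}) == pytest.approx(0.0)

    def test_bounds(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(int(rng.integers(1, 8))))
            v = popgen.pic(p)
            assert 0.0 <= v < 1.0
            assert v <= 1.0 - (p**2).sum() + 1e-12  # PIC <= He


class TestHwe:
    def test_all_heterozygotes_chi2_equals_n(self):
        g = make_table({"P": [[(100, 102)]] * 100})
        res = popgen.hwe_chisq(g, "P", "L1")
        assert res["chi2"] == pytest.approx(100.0)
        assert res["df"] == 1
        assert res["p"] < 1e-20

    def test_perfect_hwe_proportions(self):
        # 25 aa, 50 ab, 25 bb at p = q = 0.5: chi2 exactly 0
        inds = [[(100, 100)]] * 25 + [[(100, 102)]] * 50 + [[(102, 102)]] * 25
        res = popgen.hwe_chisq(make_table({"P": inds}), "P", "L1")
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert not res["low_expected"]

    def test_monomorphic_untestable(self):
        res = popgen.hwe_chisq(make_table({"P": [[(100, 100)]] * 5}), "P", "L1")
        assert not res["testable"]

    def test_low_expected_flagged(self):
        inds = [[(100, 100)]] * 9 + [[(100, 102)]]
        res = popgen.hwe_chisq(make_table({"P": inds}), "P", "L1")
        assert res["low_expected"]


class TestFStatistics:
    def test_identity_holds_per_locus(self, rng):
        for _ in range(10):
            g = random_table(rng)
            fs = popgen.f_statistics(g, n_permutations=0)
            for _, row in fs.per_locus.iterrows():
                assert (1 - row["FIT"]) == pytest.approx(
                    (1 - row["FIS"]) * (1 - row["FST"])
                )

    def test_fixed_alternative_alleles_fst_one(self):
        g = make_table({"A": [[(100, 100)]] * 5, "B": [[(102, 102)]] * 5})
        fs = popgen.f_statistics(g, n_permutations=0)
        assert fs.mean["FST"] == pytest.approx(1.0)
        assert fs.mean["Hs"] == pytest.approx(0.0)
        assert fs.mean["Ht"] == pytest.approx(0.5)

    def test_matches_oracle(self, rng):
        for _ in range(10):
            g = random_table(rng, n_pops=4, n_per_pop=5)
            fs = popgen.f_statistics(g, n_permutations=0)
            for _, row in fs.per_locus.iterrows():
                expected = nei_fstats_oracle(
                    [
                        pop_locus_genotypes(g, pop, row["locus"])
                        for pop in g.subpopulations
                    ]
                )
                for key in ("Ho", "Hs", "Ht", "FIS", "FST", "FIT"):
                    assert row[key] == pytest.approx(expected[key], abs=1e-12)

    def test_permutation_p_detects_structure(self):
        rng = np.random.default_rng(5)
        pops = {}
        for k, base in enumerate((100, 120)):
            inds = []
            for _ in range(12):
                genotype = [
                    (
                        int(base + 2 * rng.integers(0, 2)),
                        int(base + 2 * rng.integers(0, 2)),
                    )
                    for _ in range(3)
                ]
                inds.append(genotype)
            pops[f"P{k}"] = inds
        fs = popgen.f_statistics(make_table(pops), n_permutations=199, seed=1)
        # disjoint allele pools: FST is maximal, permutations cannot beat it
        assert fs.p_fst <= 0.015

    def test_permutation_p_null_uniformish(self, rng):
        g = random_table(rng, n_pops=3, n_per_pop=8, p_missing=0.0)
        fs = popgen.f_statistics(g, n_permutations=99, seed=2)
        assert 0.01 <= fs.p_fst <= 1.0
        assert 0.01 <= fs.p_fis <= 1.0


class TestNeiDistance:
    def test_hand_computed_identical_samples(self):
        # identical samples of 3, freqs 0.5/0.5: Jxy = 0.5, unbiased
        # Jx = Jy = (6*0.5 - 1)/5 = 0.4, so D = -ln(0.5/0.4) — slightly
        # negative, the expected small-sample behaviour of the estimator
        inds = [[(100, 102)], [(100, 100)], [(102, 102)]]
        g = make_table({"A": inds, "B": [list(x) for x in inds]})
        D = popgen.nei_unbiased_distance(g)
        assert D.loc["A", "B"] == pytest.approx(-math.log(0.5 / 0.4))

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            g = random_table(rng, n_pops=2, n_per_pop=8)
            D = popgen.nei_unbiased_distance(g)
            expected = nei_unbiased_distance_oracle(
                [pop_locus_genotypes(g, "P1", lc) for lc in g.loci],
                [pop_locus_genotypes(g, "P2", lc) for lc in g.loci],
            )
            assert D.loc["P1", "P2"] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        g = random_table(rng, n_pops=4, n_per_pop=6)
        D = popgen.nei_unbiased_distance(g)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_disjoint_alleles_infinite(self):
        g = make_table({"A": [[(100, 100)]] * 3, "B": [[(110, 110)]] * 3})
        D = popgen.nei_unbiased_distance(g)
        assert math.isinf(D.loc["A", "B"])


class TestGeneFlow:
    def test_values(self):
        assert popgen.gene_flow(0.2) == pytest.approx(1.0)
        assert popgen.gene_flow(0.164) == pytest.approx(1.274, abs=5e-4)
        assert popgen.gene_flow(1.0) == 0.0

    def test_domain(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                popgen.gene_flow(bad)


def _simulate_null_locus(rng, n, visible_freqs, r_null, codes=(150, 154, 158)):
    """Direct single-population HW draw with one null allele of frequency r."""
    freqs = list(visible_freqs) + [r_null]
    states = list(codes[: len(visible_freqs)]) + [0]
    genotypes = []
    for _ in range(n):
        a, b = rng.choice(len(states), size=2, p=freqs)
        ca, cb = states[int(a)], states[int(b)]
        if ca == 0 and cb == 0:
            genotypes.append([(0, 0)])
        elif ca == 0:
            genotypes.append([(cb, cb)])
        elif cb == 0:
            genotypes.append([(ca, ca)])
        else:
            genotypes.append([(ca, cb)])
    return make_table({"P": genotypes})


class TestNullAlleleEm:
    def test_recovery_fixed_r(self):
        rng = np.random.default_rng(11)
        g = _simulate_null_locus(rng, 500, (0.35, 0.25, 0.15), 0.25)
        r, p, it, conv = popgen.null_allele_em(g, "P", "L1")
        assert conv
        assert r == pytest.approx(0.25, abs=0.05)
        assert sum(p.values()) == pytest.approx(1.0 - r, abs=1e-6)

    def test_no_nulls_estimates_near_zero(self):
        rng = np.random.default_rng(12)
        g = _simulate_null_locus(rng, 500, (0.5, 0.3, 0.2), 0.0)
        r, _, _, conv = popgen.null_allele_em(g, "P", "L1")
        assert conv
        assert r == pytest.approx(0.0, abs=0.04)

    def test_monomorphic_no_blanks_zero(self):
        g = make_table({"P": [[(100, 100)]] * 10})
        r, p, it, conv = popgen.null_allele_em(g, "P", "L1")
        assert (r, conv) == (0.0, True)
        assert p == {100: 1.0}

    def test_all_blank_boundary(self):
        g = make_table({"P": [[(0, 0)]] * 4})
        r, p, _, conv = popgen.null_allele_em(g, "P", "L1")
        assert (r, conv) == (1.0, True)

    def test_estimate_all_cells(self):
        g = generate_genotypes(SynthSpec(seed=4))
        est = popgen.estimate_null_alleles(g)
        assert set(est.r_hat) <= {
            (pop, lc) for pop in g.subpopulations for lc in g.loci
        }
        assert all(0.0 <= r <= 1.0 for r in est.r_hat.values())


class TestWeirCockerham:
    def test_no_structure_near_zero(self, rng):
        # all pops drawn from one panmictic pool
        pool = [100, 102, 104, 106]
        pops = {
            f"P{k}": [
                [tuple(int(a) for a in rng.choice(pool, size=2))]
                for _ in range(50)
            ]
            for k in range(4)
        }
        theta, _ = popgen.weir_cockerham_fst(make_table(pops))
        assert abs(theta) < 0.05

    def test_full_fixation(self):
        g = make_table({"A": [[(100, 100)]] * 8, "B": [[(102, 102)]] * 8})
        theta, per_locus = popgen.weir_cockerham_fst(g)
        assert theta == pytest.approx(1.0)

    def test_fst_ena_shapes(self):
        g = generate_genotypes(SynthSpec(seed=9))
        res = popgen.fst_ena(g, n_bootstrap=50, seed=0)
        assert set(res["per_locus_uncorrected"]) == set(g.loci)
        lo, hi = res["ci_corrected"]
        assert lo <= hi
        assert -1.0 <= res["fst_corrected"] <= 1.0

    def test_fst_ena_no_nulls_agrees_with_theta(self):
        spec = SynthSpec(
            seed=21, null_rates=(0.0, 0.0, 0.0), inbreeding_f=0.0,
        )
        g = generate_genotypes(spec)
        res = popgen.fst_ena(g, n_bootstrap=0)
        theta, _ = popgen.weir_cockerham_fst(g)
        assert res["fst_uncorrected"] == pytest.approx(theta, abs=1e-12)
        # without nulls the correction should barely move the estimate
        assert res["fst_corrected"] == pytest.approx(theta, abs=0.05)


class TestAmova:
    def test_hand_worked_example(self):
        # pop A: {100,100}, {100,110}; pop B: {110,110}, {110,110}
        g = make_table(
            {"A": [[(100, 100)], [(100, 110)]], "B": [[(110, 110)], [(110, 110)]]}
        )
        res = popgen.amova(g, n_permutations=0)
        assert res.ss_among == pytest.approx(1.25)
        assert res.ss_within == pytest.approx(0.5)
        assert res.var_among == pytest.approx(0.5)
        assert res.var_within == pytest.approx(0.25)
        assert res.phi_st == pytest.approx(2 / 3)
        assert res.pct_among == pytest.approx(100 * 2 / 3)
        assert (res.df_among, res.df_within) == (1, 2)

    def test_distance_metric(self):
        g = make_table(
            {"A": [[(100, 102), (100, 100)], [(100, 104), (0, 0)]]}
        )
        D = popgen._genotype_distance_matrix(g)
        # locus 1: {100,102} vs {100,104} share one allele -> 1; locus 2 skipped
        assert D[0, 1] == pytest.approx(1.0)
        assert genotype_distance_oracle(
            [(100, 102), (100, 100)], [(100, 104), (0, 0)]
        ) == pytest.approx(1.0)

    def test_matches_oracle_random(self, rng):
        for _ in range(6):
            g = random_table(rng, n_pops=3, n_per_pop=5, p_missing=0.05)
            res = popgen.amova(g, n_permutations=0)
            expected = amova_oracle(
                [
                    [
                        [tuple(int(x) for x in g.calls[i, j]) for j in range(g.n_loci)]
                        for i in g.pop_indices(pop)
                    ]
                    for pop in g.subpopulations
                ]
            )
            assert res.ss_among == pytest.approx(expected["ss_among"], abs=1e-9)
            assert res.ss_within == pytest.approx(expected["ss_within"], abs=1e-9)
            assert res.var_among == pytest.approx(expected["var_among"], abs=1e-9)
            assert res.phi_st == pytest.approx(expected["phi_st"], abs=1e-9)

    def test_identical_pops_phi_zero(self):
        inds = [[(100, 102)], [(100, 100)], [(102, 102)]]
        g = make_table({"A": inds, "B": [list(x) for x in inds]})
        res = popgen.amova(g, n_permutations=49, seed=0)
        assert res.phi_st == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.1

    def test_singleton_pop_excluded(self):
        g = make_table(
            {
                "A": [[(100, 100)], [(100, 102)]],
                "B": [[(102, 102)], [(102, 102)]],
                "C": [[(104, 104)]],
            }
        )
        res = popgen.amova(g, n_permutations=0)
        assert res.df_among == 1  # C dropped

    def test_structure_significant(self):
        g = make_table({"A": [[(100, 100)]] * 6, "B": [[(110, 110)]] * 6})
        res = popgen.amova(g, n_permutations=199, seed=3)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value < 0.05


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        X = rng.normal(size=(7, 2))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        res = popgen.pcoa(D)
        Y = res["coordinates"][:, :2]
        # Euclidean distances are reproduced exactly
        DY = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
        assert np.allclose(DY, D, atol=1e-8)
        assert res["pct_variance"].sum() == pytest.approx(100.0)

    def test_names_carried_from_dataframe(self):
        D = pd.DataFrame(
            [[0, 1.0], [1.0, 0]], index=["a", "b"], columns=["a", "b"]
        )
        assert popgen.pcoa(D)["names"] == ["a", "b"]

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            popgen.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestEvanno:
    @staticmethod
    def _table():
        means = {1: -6000.0, 2: -5500.0, 3: -4000.0, 4: -3950.0, 5: -3900.0}
        rows = []
        for k, m in means.items():
            for d in (-10.0, 0.0, 10.0):
                rows.append({"K": k, "lnp": m + d})
        return pd.DataFrame(rows)

    def test_hand_computed_elbow(self):
        out = popgen.evanno_delta_k(self._table())
        by_k = out.set_index("K")
        # sd of (-10, 0, 10) is 10; second differences 1000, 1450, 0
        assert by_k.loc[2, "delta_k"] == pytest.approx(100.0)
        assert by_k.loc[3, "delta_k"] == pytest.approx(145.0)
        assert by_k.loc[4, "delta_k"] == pytest.approx(0.0)
        assert out.attrs["best_k"] == 3
        assert math.isnan(by_k.loc[1, "delta_k"])  # endpoints undefined

    def test_input_validation(self):
        with pytest.raises(ValueError, match="consecutive"):
            popgen.evanno_delta_k(
                pd.DataFrame({"K": [1, 1, 3, 3, 5, 5], "lnp": [0.0] * 6})
            )
        with pytest.raises(ValueError, match="replicates"):
            popgen.evanno_delta_k(
                pd.DataFrame({"K": [1, 2, 3], "lnp": [0.0, 1.0, 2.0]})
            )

    def test_zero_sd_flagged(self):
        rows = [
            {"K": k, "lnp": v}
            for k, v in ((1, -10.0), (1, -10.0), (2, -5.0), (2, -5.0),
                         (3, -4.0), (3, -4.0))
        ]
        out = popgen.evanno_delta_k(pd.DataFrame(rows)).set_index("K")
        assert out.loc[2, "sd_zero"]
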