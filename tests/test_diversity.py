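"""Per-locus diversity statistics against hand-computed oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import equimhc as eq
from equimhc import UndefinedStatisticError
from equimhc.diversity import AlleleFreqTable


def table(counts, n_genes=None):
    n = n_genes if n_genes is not None else sum(counts.values())
    return AlleleFreqTable("X", counts, n)


def one_locus_dataset(genotypes, pop="P"):
    panel = eq.LocusPanel((eq.LocusDef("X", "I", 0),))
    inds = [
        eq.Individual(f"i{k}", pop, {"X": g}) for k, g in enumerate(genotypes)
    ]
    return eq.PopulationDataset(panel=panel, individuals=inds)


class TestAlleleFrequencies:
    def test_counts_and_n_genes(self):
        ds = one_locus_dataset([(226, 230)] * 10)
        t = eq.allele_frequencies(ds, "P", "X")
        assert t.freqs == {226: 0.5, 230: 0.5} and t.n_genes == 20

    def test_homozygote_weighting(self):
        ds = one_locus_dataset([(226, 226), (226, 230)])
        t = eq.allele_frequencies(ds, "P", "X")
        assert t.freqs == {226: 0.75, 230: 0.25}

    def test_matches_simulator_sampling_distribution(self):
        # founder alleles are drawn from the pool haplotype frequencies;
        # realized gene counts should pass a chi-square GOF test
        cfg = eq.SimConfig(
            panel=eq.default_panel(),
            populations=[eq.PopulationConfig("P", 300, 200, 0)],
            founder_allele_counts=dict.fromkeys(eq.default_panel().names, 6),
            crossover_prob=0, conversion_prob=0, indel_prob=0, seed=3,
        )
        ds, truth = eq.simulate_dataset(cfg)
        pool = truth.pools["P"]
        for j, locus in enumerate(ds.panel.names[:4]):
            expected = {}
            for hap in pool:
                expected[hap[j]] = expected.get(hap[j], 0) + 1 / len(pool)
            t = eq.allele_frequencies(ds, "P", locus)
            alleles = sorted(set(expected) | set(t.counts))
            obs = np.array([t.counts.get(a, 0) for a in alleles], dtype=float)
            exp = np.array([expected.get(a, 0) * t.n_genes for a in alleles])
            keep = exp > 0
            assert obs[~keep].sum() == 0
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            p = sps.chi2.sf(chi2, keep.sum() - 1)
            assert p > 0.001


class TestHeterozygosityAndPic:
    def test_observed_extremes(self):
        assert eq.observed_heterozygosity(one_locus_dataset([(1, 1)] * 5), "P", "X") == 0.0
        assert eq.observed_heterozygosity(one_locus_dataset([(1, 2)] * 5), "P", "X") == 1.0

    def test_he_unbiased_hand_value(self):
        # p = (.5, .5), 2n = 20 -> (20/19) * .5
        assert eq.expected_heterozygosity(table({1: 10, 2: 10})) == pytest.approx(20 / 19 * 0.5)

    def test_he_monomorphic_zero_and_undefined(self):
        assert eq.expected_heterozygosity(table({1: 10})) == 0.0
        with pytest.raises(UndefinedStatisticError):
            eq.expected_heterozygosity(table({1: 1}, n_genes=1))

    def test_pic_hand_value_and_bound(self):
        assert eq.pic(table({1: 10})) == 0.0
        assert eq.pic(table({1: 10, 2: 10})) == pytest.approx(0.375)
        rng = np.random.default_rng(4)
        for _ in range(200):
            k = rng.integers(2, 8)
            counts = {i: int(c) for i, c in enumerate(rng.integers(1, 40, k))}
            t = table(counts)
            assert 0.0 <= eq.pic(t) <= eq.expected_heterozygosity(t) <= 1.0


class TestFisAndNullAlleles:
    def test_fis_zero_when_ho_equals_he(self):
        assert eq.fis(0.5, 0.5) == 0.0

    def test_fis_undefined_at_zero_he(self):
        with pytest.raises(UndefinedStatisticError):
            eq.fis(0.0, 0.0)

    def test_weir_cockerham_f_sign_agrees(self):
        # strong heterozygote deficit -> both estimators positive
        ds = one_locus_dataset([(1, 1)] * 8 + [(2, 2)] * 8 + [(1, 2)] * 2)
        t = eq.allele_frequencies(ds, "P", "X")
        f_ratio = eq.fis(
            eq.observed_heterozygosity(ds, "P", "X"), eq.expected_heterozygosity(t)
        )
        f_wc = eq.fis_weir_cockerham(ds, "P", "X")
        assert f_ratio > 0 and f_wc > 0

    def test_null_frequency_values(self):
        assert eq.null_allele_frequency(0.5, 0.5) == 0.0
        assert eq.null_allele_frequency(0.4, 0.8) == pytest.approx(1 / 3)
        assert eq.null_allele_frequency(0.62, 0.83) == pytest.approx(0.14, abs=0.005)


class TestAllelicRichness:
    def test_no_rarefaction_gives_raw_count(self):
        ds = one_locus_dataset([(1, 1), (1, 2)])
        assert eq.allelic_richness(ds, "P", "X", g=4) == pytest.approx(2.0)

    def test_matches_subsample_enumeration(self):
        # counts {A:3, B:1}, g=2: average distinct alleles over all C(4,2)
        ds = one_locus_dataset([(1, 1), (1, 2)])
        genes = [1, 1, 1, 2]
        oracle = np.mean(
            [len(set(c)) for c in itertools.combinations(genes, 2)]
        )
        assert eq.allelic_richness(ds, "P", "X", g=2) == pytest.approx(oracle)

    def test_g_beyond_sample_is_an_error(self):
        ds = one_locus_dataset([(1, 2)])
        with pytest.raises(ValueError):
            eq.allelic_richness(ds, "P", "X", g=3)


class TestEffectivePrivateAlleles:
    def two_pop_dataset(self):
        panel = eq.LocusPanel((eq.LocusDef("X", "I", 0),))
        inds = [
            eq.Individual("a1", "A", {"X": (1, 2)}),
            eq.Individual("a2", "A", {"X": (1, 2)}),
            eq.Individual("b1", "B", {"X": (3, 3)}),
            eq.Individual("b2", "B", {"X": (3, 3)}),
        ]
        return eq.PopulationDataset(panel=panel, individuals=inds)

    def test_effective_alleles_even_frequencies(self):
        ds = self.two_pop_dataset()
        na, ne, _ = eq.effective_and_private_alleles(ds, "A")
        assert na == 2.0 and ne == pytest.approx(2.0)

    def test_private_alleles_fixed_differences(self):
        ds = self.two_pop_dataset()
        assert eq.effective_and_private_alleles(ds, "A")[2] == 2.0
        assert eq.effective_and_private_alleles(ds, "B")[2] == 1.0

    def test_single_population_undefined(self):
        ds = one_locus_dataset([(1, 2)])
        with pytest.raises(UndefinedStatisticError):
            eq.effective_and_private_alleles(ds, "P")


class TestHomogeneityTest:
    def test_identical_tables_give_null(self, panel):
        inds = [
            eq.Individual(f"{p}{k}", p, {n: (1, 2) for n in panel.names})
            for p in ("A", "B") for k in range(10)
        ]
        ds = eq.PopulationDataset(panel=panel, individuals=inds)
        chi2, df, p, pb = eq.allele_freq_homogeneity_test(ds, "COR110")
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_fixed_difference_hand_chi_square(self):
        # gene-count table [[20, 0], [0, 20]] -> chi2 = 40
        ds = eq.PopulationDataset(
            panel=eq.LocusPanel((eq.LocusDef("X", "I", 0),)),
            individuals=[
                *[eq.Individual(f"a{k}", "A", {"X": (1, 1)}) for k in range(10)],
                *[eq.Individual(f"b{k}", "B", {"X": (2, 2)}) for k in range(10)],
            ],
        )
        chi2, df, p, pb = eq.allele_freq_homogeneity_test(ds, "X", n_loci_tested=11)
        assert chi2 == pytest.approx(40.0)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(40, 1))
        assert pb == pytest.approx(min(1.0, p * 11))

    def test_bonferroni_capped_at_one(self):
        ds = eq.PopulationDataset(
            panel=eq.LocusPanel((eq.LocusDef("X", "I", 0),)),
            individuals=[
                eq.Individual("a", "A", {"X": (1, 2)}),
                eq.Individual("b", "B", {"X": (1, 2)}),
            ],
        )
        _, _, _, pb = eq.allele_freq_homogeneity_test(ds, "X", n_loci_tested=11)
        assert pb == 1.0


class TestEvannoDeltaK:
    def test_linear_lnp_gives_zero_delta_k(self):
        lnp = {k: [-10.0 * k + e for e in (-0.5, 0.5)] for k in range(2, 7)}
        res = eq.evanno_delta_k(lnp)
        interior = res.table.dropna(subset=["delta_k"])
        assert np.allclose(interior["delta_k"], 0.0)

    def test_hand_computed_second_difference(self):
        lnp = {2: [-101, -99], 3: [-82, -78], 4: [-79.25, -79.75], 5: [-79.5, -78.5]}
        res = eq.evanno_delta_k(lnp)
        row3 = res.table[res.table.K == 3].iloc[0]
        assert row3["l2"] == pytest.approx(19.5)
        assert row3["delta_k"] == pytest.approx(19.5 / np.std([-82, -78], ddof=1))
        row4 = res.table[res.table.K == 4].iloc[0]
        assert row4["delta_k"] == pytest.approx(0.0)
        assert res.best_k == 3

    def test_zero_sd_flagged_infinite(self):
        lnp = {2: [-10, -10], 3: [-8, -8], 4: [-7.9, -7.8]}
        res = eq.evanno_delta_k(lnp)
        assert math.isinf(res.table[res.table.K == 3].iloc[0]["delta_k"])

    def test_requires_three_ks_and_replicates(self):
        with pytest.raises(ValueError):
            eq.evanno_delta_k({2: [-1, -2], 3: [-1, -2]})
        with pytest.raises(ValueError):
            eq.evanno_delta_k({2: [-1], 3: [-1], 4: [-1]})


class TestStatsTable:
    def test_bounds_hold_on_simulated_data(self, study_sim):
        ds, _ = study_sim
        stats = eq.locus_stats(ds, "Pop2", n_mc=500, seed=9)
        assert len(stats) == 11
        for s in stats:
            assert 0.0 <= s.Ho <= 1.0
            assert 0.0 <= s.PIC <= s.He <= 1.0
            assert s.n_alleles >= 1 and s.AR <= s.n_alleles + 1e-9
            assert 0.0 <= s.hwe_p <= 1.0

    def test_population_summary_shape(self, study_sim):
        ds, _ = study_sim
        frame = eq.population_summary(ds)
        assert list(frame["population"]) == ["Pop1", "Pop2", "Pop3"]
        assert ((frame["He"] >= 0) & (frame["He"] <= 1)).all()
        assert (frame["Ne"] >= 1).all()
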