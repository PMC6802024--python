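"""Population-genetic statistics against closed forms, enumeration oracles
and parametric simulation."""

import itertools
import math

import numpy as np
import pytest

from ormiapop.genotype_data import GenotypeDataset, LocusInfo
from ormiapop.popgen_stats import (
    allele_frequencies,
    garza_williamson_m,
    heterozygosity,
    hwe_exact_enumeration,
    hwe_permutation_test,
    nei_distance,
    pairwise_fst_wc,
    rarefied_allelic_richness,
    rarefied_private_alleles,
    weir_cockerham_theta,
)

from conftest import make_dataset


def single_pop(genotypes, motif=4, pop="P"):
    return make_dataset({pop: [[g] for g in genotypes]}, motif=motif)


def freqs_from_counts(pop_counts):
    """AlleleFrequencyTable from {pop: {allele: copies}} at one locus, via a
    literal dataset (so the table always matches a constructible dataset)."""
    geno = {}
    for pop, counts in pop_counts.items():
        copies = [a for a, k in counts.items() for _ in range(k)]
        geno[pop] = [[(copies[i], copies[i + 1])] for i in range(0, len(copies), 2)]
    return allele_frequencies(make_dataset(geno))


class TestAlleleFrequencies:
    def test_counts_aa_ab(self):
        ds = single_pop([(100, 100), (100, 104)])
        f = allele_frequencies(ds)
        assert f.counts["P"]["L1"] == {100: 3, 104: 1}
        assert f.n_copies("P", "L1") == 4

    def test_all_missing_locus_absent(self):
        ds = make_dataset({"P": [[None, (100, 104)], [None, (100, 100)]]})
        f = allele_frequencies(ds)
        assert "L1" not in f.counts["P"]
        assert f.n_copies("P", "L1") == 0

    def test_copies_conserved(self, rng):
        sizes = 100 + 4 * rng.integers(0, 6, size=(12, 3, 2))
        ds = make_dataset(
            {"P": [[tuple(sizes[i, j]) for j in range(3)] for i in range(12)]}
        )
        f = allele_frequencies(ds)
        for locus in f.loci:
            assert f.n_copies("P", locus) == 2 * 12


class TestHeterozygosity:
    def test_monomorphic_zero(self):
        ds = single_pop([(100, 100)] * 5)
        s = heterozygosity(allele_frequencies(ds), ds)["P"]
        assert s.h_exp == 0.0 and s.h_obs == 0.0

    def test_half_half_closed_form(self):
        # 10 individuals, all heterozygous 100/104: p = q = 0.5
        ds = single_pop([(100, 104)] * 10)
        s = heterozygosity(allele_frequencies(ds), ds)["P"]
        assert s.h_exp == pytest.approx(0.5)
        assert s.h_obs == pytest.approx(1.0)
        assert s.h_exp_unbiased == pytest.approx(20 / 19 * 0.5)

    def test_uses_locus_specific_sample_sizes(self):
        # locus 2 scored in only 2 individuals, one heterozygous
        ds = make_dataset(
            {"P": [[(100, 104), (210, 213)], [(100, 104), (210, 210)],
                   [(100, 104), None], [(100, 104), None]]}
        )
        s = heterozygosity(allele_frequencies(ds), ds)["P"]
        assert s.h_obs == pytest.approx((1.0 + 0.5) / 2)


class TestRarefaction:
    def test_g1_is_one(self):
        f = freqs_from_counts({"P": {100: 3, 104: 5}})
        assert rarefied_allelic_richness(f, 1).loc["P", "L1"] == pytest.approx(1.0)

    def test_g_equals_n_gives_observed(self):
        f = freqs_from_counts({"P": {100: 3, 104: 5, 108: 2}})
        assert rarefied_allelic_richness(f, 10).loc["P", "L1"] == pytest.approx(3.0)

    def test_enumeration_oracle(self):
        # counts {3, 1}, g = 2: enumerate all C(4,2) subsamples
        copies = [100, 100, 100, 104]
        expected = np.mean(
            [len(set(c)) for c in itertools.combinations(copies, 2)]
        )
        assert expected == pytest.approx(1.5)
        f = freqs_from_counts({"P": {100: 3, 104: 1}})
        assert rarefied_allelic_richness(f, 2).loc["P", "L1"] == pytest.approx(expected)

    def test_monotone_in_g(self):
        f = freqs_from_counts({"P": {100: 5, 104: 3, 108: 2, 112: 2}})
        vals = [rarefied_allelic_richness(f, g).loc["P", "L1"] for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_g(self):
        f = freqs_from_counts({"P": {100: 3, 104: 1}})
        with pytest.raises(ValueError, match="g must be"):
            rarefied_allelic_richness(f, 0)


class TestPrivateAlleles:
    def test_fixed_private_allele_at_full_g(self):
        f = freqs_from_counts({"A": {100: 4}, "B": {104: 4}})
        priv = rarefied_private_alleles(f, 4)
        assert priv["A"] == pytest.approx(1.0)
        assert priv["B"] == pytest.approx(1.0)

    def test_identical_populations_few_private(self):
        f = freqs_from_counts({"A": {100: 3, 104: 1}, "B": {100: 3, 104: 1}})
        priv = rarefied_private_alleles(f, 4)
        assert priv["A"] == priv["B"]
        assert priv["A"] < 0.35  # both alleles nearly always shared at g = N

    def test_enumeration_oracle(self):
        # pops {A:3, B:1} and {A:4}, g = 2: enumerate subsample pairs
        pop1 = [100, 100, 100, 104]
        pop2 = [100, 100, 100, 100]
        total = n = 0
        for c1 in itertools.combinations(range(4), 2):
            for c2 in itertools.combinations(range(4), 2):
                s1 = {pop1[i] for i in c1}
                s2 = {pop2[i] for i in c2}
                total += len(s1 - s2)
                n += 1
        expected = total / n
        f = freqs_from_counts({"P1": {100: 3, 104: 1}, "P2": {100: 4}})
        assert rarefied_private_alleles(f, 2)["P1"] == pytest.approx(expected)

    def test_g_too_large_names_population(self):
        f = freqs_from_counts({"A": {100: 3, 104: 1}, "B": {100: 2}})
        with pytest.raises(ValueError, match="B"):
            rarefied_private_alleles(f, 3)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        ds = make_dataset(
            {"A": [[(100, 100)]] * 6, "B": [[(104, 104)]] * 6}
        )
        assert weir_cockerham_theta(ds) == pytest.approx(1.0)

    def test_panmictic_centred_on_zero(self, rng):
        thetas = []
        for _ in range(200):
            copies = rng.choice([100, 104, 108], size=(20, 2), p=[0.5, 0.3, 0.2])
            ds = make_dataset(
                {
                    "A": [[tuple(copies[i])] for i in range(10)],
                    "B": [[tuple(copies[i])] for i in range(10, 20)],
                }
            )
            thetas.append(weir_cockerham_theta(ds))
        assert abs(np.mean(thetas)) < 0.01

    def test_balding_nichols_calibration(self, rng):
        # parametric oracle: p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F) gives E[theta]=F
        F = 0.15
        n_loci, n_ind = 150, 80
        geno = {"A": [[] for _ in range(n_ind)], "B": [[] for _ in range(n_ind)]}
        for _ in range(n_loci):
            p = rng.uniform(0.2, 0.8)
            a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
            for pop in ("A", "B"):
                pi = rng.beta(a, b)
                draws = rng.random((n_ind, 2)) < pi
                for i in range(n_ind):
                    pair = tuple(100 + 4 * draws[i].astype(int))
                    geno[pop][i].append(pair)
        ds = make_dataset(geno)
        assert weir_cockerham_theta(ds) == pytest.approx(F, abs=0.03)

    def test_pairwise_matrix_symmetric_with_flags(self):
        ds = make_dataset(
            {
                "A": [[(100, 104)], [(100, 100)], [(104, 104)]],
                "B": [[(100, 104)], [(104, 104)], [(100, 104)]],
                "C": [[(108, 108)], [(108, 108)], [(108, 104)]],
            }
        )
        m = pairwise_fst_wc(ds)
        assert np.allclose(m.values, m.values.T)
        assert m.allow_negative  # negative estimates reported verbatim

    def test_too_few_individuals_nan(self):
        ds = make_dataset({"A": [[(100, 104)]], "B": [[(100, 100)], [(104, 104)]]})
        with pytest.warns(UserWarning, match="usable"):
            assert math.isnan(weir_cockerham_theta(ds, ["A", "B"]))


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        f = freqs_from_counts({"A": {100: 2, 104: 2}, "B": {100: 2, 104: 2}})
        assert nei_distance(f)["A", "B"] == pytest.approx(0.0)

    def test_hand_example(self):
        # p1 = (.5, .5), p2 = (.9, .1): I = 0.5/sqrt(0.41), D = -ln I
        f = freqs_from_counts(
            {"A": {100: 5, 104: 5}, "B": {100: 9, 104: 1}}
        )
        expected = -math.log(0.5 / math.sqrt(0.41))
        assert nei_distance(f)["A", "B"] == pytest.approx(expected, abs=1e-9)

    def test_disjoint_alleles_infinite(self):
        f = freqs_from_counts({"A": {100: 4}, "B": {104: 4}})
        assert nei_distance(f)["A", "B"] == math.inf

    def test_no_shared_loci_errors(self):
        ds = make_dataset(
            {"A": [[(100, 100), None]], "B": [[None, (210, 210)]]}
        )
        with pytest.raises(ValueError, match="share no scored loci"):
            nei_distance(allele_frequencies(ds))


class TestGarzaWilliamson:
    @pytest.mark.parametrize(
        "alleles, motif, expected",
        [
            ([100, 104, 108], 4, 1.0),  # full ladder: k=3, r=2
            ([100, 108], 4, 2 / 3),  # gapped ladder: k=2, r=2
            ([100], 4, 1.0),  # monomorphic
        ],
    )
    def test_ladder_cases(self, alleles, motif, expected):
        geno = [(a, a) for a in alleles] or [(100, 100)]
        ds = single_pop(geno, motif=motif)
        m = garza_williamson_m(ds)
        assert m.loc["P", "L1"] == pytest.approx(expected)

    def test_non_divisible_range_rounds_with_warning(self):
        ds = single_pop([(100, 100), (106, 106)], motif=4)
        with pytest.warns(UserWarning, match="rounded"):
            m = garza_williamson_m(ds)
        # r = 6/4 -> rounds to 2, M = 2/3
        assert m.loc["P", "L1"] == pytest.approx(2 / 3)

    def test_bottleneck_lowers_m(self, rng):
        """Terminal founder populations show lower mean M than the ancestral
        range (drift prunes alleles faster than it shrinks the size range)."""
        from ormiapop.synthetic_data import ChainStep, FounderChainConfig, simulate_genotypes

        cfg = FounderChainConfig(
            chain=[
                ChainStep("anc", 300, 5, 300, 25),
                ChainStep("mid", 10, 10, 100, 25),
                ChainStep("tip", 4, 10, 100, 25),
            ],
            n_loci=8,
            mutation_rate=0.0,
        )
        wins = 0
        for rep in range(100):
            ds, _ = simulate_genotypes(cfg, seed=5000 + rep)
            m = garza_williamson_m(ds)["mean"]
            wins += m["tip"] < m["anc"]
        assert wins > 50


class TestHWE:
    def test_monomorphic_p_one(self):
        ds = single_pop([(100, 100)] * 6)
        res = hwe_permutation_test(ds, "P", "L1", 99, seed=0)
        assert res.p_value == 1.0 and res.monomorphic

    def test_needs_five_genotypes(self):
        ds = single_pop([(100, 104)] * 4)
        with pytest.raises(ValueError, match=">= 5"):
            hwe_permutation_test(ds, "P", "L1", 99, seed=0)

    def test_extreme_het_excess_small_p(self):
        # 50 individuals all heterozygous 100/104
        ds = single_pop([(100, 104)] * 50)
        res = hwe_permutation_test(ds, "P", "L1", 9999, seed=7)
        assert res.p_value < 0.01

    def test_exact_enumeration_matches_tail(self):
        """Small-sample cross-check: the Monte-Carlo tail probability agrees
        with full enumeration under Levene's conditional distribution."""
        ds = single_pop([(100, 104)] * 5 + [(100, 100)])
        exact = hwe_exact_enumeration(ds, "P", "L1")
        mc = hwe_permutation_test(ds, "P", "L1", 20000, seed=3)
        assert exact.observed_het == mc.observed_het == 5
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_exact_distribution_normalised(self):
        from ormiapop.popgen_stats import _enumerate_het_distribution

        dist = _enumerate_het_distribution([5, 4, 3])
        assert sum(dist.values()) == pytest.approx(1.0)
        # two odd allele counts force at least one heterozygote, and the
        # heterozygote count can never exceed the number of genotypes
        assert min(dist) == 1 and max(dist) <= 6
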