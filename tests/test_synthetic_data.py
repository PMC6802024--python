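"""The serial-founder study generator: drift theory, determinism, round
trips through the pipeline's readers."""

import numpy as np
import pytest

from ormiapop.genotype_data import read_genotypes
from ormiapop.haplotype_network import collapse_haplotypes, read_alignment
from ormiapop.popgen_stats import allele_frequencies, heterozygosity
from ormiapop.song_distance import (
    encode_song_features,
    read_assemblages,
    read_song_table,
    species_song_distance,
)
from ormiapop.synthetic_data import (
    ChainStep,
    FounderChainConfig,
    default_scenario,
    simulate_coi,
    simulate_genotypes,
    simulate_songs,
    simulate_study,
    write_bundle,
)


def small_chain(**kw):
    defaults = dict(
        chain=[
            ChainStep("anc", 200, 5, 200, 20),
            ChainStep("mid", 8, 8, 100, 20),
            ChainStep("tip", 4, 8, 100, 20),
        ],
        n_loci=6,
    )
    defaults.update(kw)
    return FounderChainConfig(**defaults)


class TestGenotypeSimulation:
    def test_no_drift_limit_recovers_ancestral_frequencies(self):
        """Huge founder pools, no drift generations, no mutation: sampled
        frequencies sit within binomial error of the ancestral draw."""
        cfg = FounderChainConfig(
            chain=[ChainStep("big", 5000, 0, 5000, 400)],
            n_loci=4,
            n_ancestral_alleles=4,
            mutation_rate=0.0,
        )
        ds, truth = simulate_genotypes(cfg, seed=11)
        freqs = allele_frequencies(ds)
        for locus, true_f in truth.allele_frequencies["big"].items():
            obs = freqs.frequencies("big", locus)
            for size, p in true_f.items():
                n = 2 * 400
                se = np.sqrt(p * (1 - p) / n)
                assert abs(obs.get(int(size), 0.0) - p) < 5 * se + 1e-9

    def test_heterozygosity_declines_along_bottleneck_chain(self):
        """Replicate-mean expected heterozygosity decreases strictly along a
        chain of severe founder events (drift theory: E[H_t] = H_0
        (1 - 1/2N)^t compounded by each founding)."""
        cfg = small_chain(mutation_rate=0.0)
        h = {"anc": [], "mid": [], "tip": []}
        for rep in range(100):
            _, truth = simulate_genotypes(cfg, seed=3000 + rep)
            for pop in h:
                h[pop].append(truth.expected_h_trajectory[pop])
        assert np.mean(h["anc"]) > np.mean(h["mid"]) > np.mean(h["tip"])

    def test_terminal_alleles_subset_of_source_without_mutation(self):
        cfg = small_chain(mutation_rate=0.0)
        ok = 0
        for rep in range(50):
            _, truth = simulate_genotypes(cfg, seed=4000 + rep)
            sub = all(
                set(truth.allele_frequencies["tip"][loc])
                <= set(truth.allele_frequencies["mid"][loc])
                for loc in truth.allele_frequencies["tip"]
            )
            ok += sub
        assert ok >= 48  # >= 95% of no-mutation replicates

    def test_mutation_can_create_novel_alleles(self):
        cfg = small_chain(mutation_rate=0.05)
        novel = 0
        for rep in range(10):
            _, truth = simulate_genotypes(cfg, seed=6000 + rep)
            for loc in truth.allele_frequencies["tip"]:
                if not (
                    set(truth.allele_frequencies["tip"][loc])
                    <= set(truth.allele_frequencies["anc"][loc])
                ):
                    novel += 1
        assert novel > 0

    def test_missingness_injection(self):
        cfg = small_chain(missing_rate=0.2)
        ds, _ = simulate_genotypes(cfg, seed=2)
        frac = ds.missing_mask().mean()
        assert 0.1 < frac < 0.3

    def test_determinism(self):
        cfg = small_chain()
        d1, t1 = simulate_genotypes(cfg, seed=99)
        d2, t2 = simulate_genotypes(cfg, seed=99)
        assert np.array_equal(d1.calls, d2.calls)
        assert t1.allele_frequencies == t2.allele_frequencies

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="founder_size"):
            ChainStep("x", 100, 1, 50, 10)
        with pytest.raises(ValueError, match="concentration"):
            FounderChainConfig(chain=[ChainStep("x", 5, 1, 10, 5)],
                               dirichlet_concentration=0.0)


class TestCOISimulation:
    def test_theta_zero_single_haplotype(self):
        aln = simulate_coi(10, length=100, theta=0.0, seed=1)
        assert collapse_haplotypes(aln).n_haplotypes == 1

    def test_star_pairwise_differences_expectation(self):
        """Star genealogy: E[pairwise diff] = 2 x mean branch mutations."""
        theta = 6.0
        diffs = []
        for rep in range(40):
            aln = simulate_coi(12, length=2000, genealogy="star",
                               theta=theta, seed=100 + rep)
            seqs = [s for _p, s in aln.records.values()]
            arr = np.array([list(s) for s in seqs])
            for i in range(0, 12, 3):
                for j in range(i + 1, min(i + 3, 12)):
                    diffs.append(np.sum(arr[i] != arr[j]))
        # mean over ~320 pairs; homoplasy at 2000 sites is negligible
        assert np.mean(diffs) == pytest.approx(theta, rel=0.15)

    def test_watterson_segregating_sites(self):
        """Coalescent mode: E[S] = theta * sum_{i<n} 1/i."""
        theta, n = 5.0, 15
        expected = theta * sum(1 / i for i in range(1, n))
        S = []
        for rep in range(60):
            aln = simulate_coi(n, length=3000, genealogy="coalescent",
                               theta=theta, seed=200 + rep)
            arr = np.array([list(s) for _p, s in aln.records.values()])
            S.append(np.sum([len(set(col)) > 1 for col in arr.T]))
        assert np.mean(S) == pytest.approx(expected, rel=0.15)

    def test_bad_genealogy(self):
        with pytest.raises(ValueError, match="genealogy"):
            simulate_coi(5, genealogy="ladder", seed=0)


class TestSongSimulation:
    def test_zero_variance_identical_species(self):
        laws = {
            "dominant_freq": (4.5, 0.0),
            "pulse_rate": (40.0, 0.0),
            "pulses_per_unit": (2.0, 0.0),
            "duty_cycle": (0.5, 0.0),
            "song_type_probs": (1.0, 0.0, 0.0, 0.0),
        }
        recs = simulate_songs(5, laws, seed=1)
        dm = species_song_distance(encode_song_features(recs))
        assert np.allclose(dm.values, 0.0)

    def test_shifted_species_dominates_distances(self):
        laws = {
            "dominant_freq": (4.5, 0.0),
            "pulse_rate": (40.0, 0.0),
            "pulses_per_unit": (2.0, 0.0),
            "duty_cycle": (0.5, 0.0),
            "song_type_probs": (1.0, 0, 0, 0),
        }
        recs = simulate_songs(6, laws, seed=2)
        recs[0].dominant_freq += 50.0
        dm = species_song_distance(encode_song_features(recs))
        shifted = recs[0].species
        others = [r.species for r in recs[1:]]
        min_to_shifted = min(dm[shifted, o] for o in others)
        max_between_others = max(
            dm[a, b] for i, a in enumerate(others) for b in others[i + 1 :]
        )
        assert min_to_shifted > max_between_others

    def test_seeded_determinism(self):
        r1 = simulate_songs(8, seed=42)
        r2 = simulate_songs(8, seed=42)
        assert [(r.species, r.song_type, r.dominant_freq) for r in r1] == [
            (r.species, r.song_type, r.dominant_freq) for r in r2
        ]

    def test_records_satisfy_invariants(self):
        # constructing SongRecord validates conditional-field consistency
        recs = simulate_songs(40, seed=7)
        assert len(recs) == 40


class TestStudyBundle:
    def test_bundle_round_trips_through_readers(self, tmp_path):
        cfg = small_chain()
        bundle = simulate_study(cfg, seed=5, out_dir=tmp_path)
        ds = read_genotypes(tmp_path / "genotypes.tsv")
        assert np.array_equal(ds.calls, bundle.genotypes.calls)
        aln = read_alignment(tmp_path / "coi.fasta")
        assert aln.n == bundle.alignment.n
        songs = read_song_table(tmp_path / "songs.tsv")
        assert len(songs) == cfg.n_species
        asm = read_assemblages(tmp_path / "assemblages.tsv")
        assert [a.population for a in asm] == [s.name for s in cfg.chain]

    def test_same_seed_bit_identical_files(self, tmp_path):
        cfg = small_chain()
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        simulate_study(cfg, seed=77, out_dir=d1)
        simulate_study(cfg, seed=77, out_dir=d2)
        for name in ["genotypes.tsv", "coi.fasta", "songs.tsv",
                     "assemblages.tsv", "coordinates.tsv", "truth.json"]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_default_scenario_shape(self):
        cfg = default_scenario()
        assert [s.name for s in cfg.chain][0] == "Florida"
        assert [s.name for s in cfg.chain][-1] == "Hilo"
        bundle = simulate_study(cfg, seed=1)
        assert bundle.genotypes.n_individuals == sum(
            s.sample_size for s in cfg.chain
        )
        assert set(bundle.coordinates) == {s.name for s in cfg.chain}

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = small_chain()
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = FounderChainConfig.from_yaml(p)
        assert back == cfg

    def test_zero_turnover_shared_hosts_degenerate_distance(self):
        """With no assemblage turnover every population shares hosts, the
        population song matrix is all zeros, and Mantel refuses the
        zero-variance triangle."""
        from ormiapop.matrix_tests import geographic_distances, mantel
        from ormiapop.song_distance import population_song_distance

        cfg = small_chain(assemblage_turnover=0)
        bundle = simulate_study(cfg, seed=3)
        dm = species_song_distance(encode_song_features(bundle.songs))
        pm = population_song_distance(dm, bundle.assemblages, "min_common")
        assert np.allclose(pm.values, 0.0)
        geo = geographic_distances(bundle.coordinates)
        # need >= 4 labels for mantel; 3-pop chain hits the size guard first
        with pytest.raises(ValueError):
            mantel(pm, geo, 9, seed=0)
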