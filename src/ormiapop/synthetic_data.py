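"""Synthetic serial-founder studies with recorded ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: an ancestral population at one end of a linear colonisation chain,
a founder event (a finite multinomial draw of gene copies) at every step,
Wright-Fisher drift between steps, stepwise mutation on a microsatellite
size ladder, a single maternally inherited sequence locus whose haplotype
diversity erodes along the chain, host-song assemblages that turn over with
position, and populations placed along a geographic transect.  Every draw
flows from one seed, so a bundle is bit-identical under the same
configuration and seed, and a :class:`TruthRecord` stores the realized
allele frequencies and expected-heterozygosity trajectory for recovery
tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genotype_data import MISSING, GenotypeDataset, LocusInfo, write_genotypes
from .haplotype_network import SequenceAlignment, write_alignment
from .song_distance import HostAssemblage, SongRecord, SongType

__all__ = [
    "ChainStep",
    "FounderChainConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_coi",
    "simulate_songs",
    "simulate_study",
    "default_scenario",
    "strong_ibd_scenario",
]

KM_PER_DEGREE = 111.19  # great-circle km per degree along the equator


@dataclass(frozen=True)
class ChainStep:
    """One population in the colonisation chain."""

    name: str
    founder_size: int  # N_f diploid founders drawn from the source
    generations: int  # drift generations at census size before sampling
    census_size: int  # diploid census size N during drift
    sample_size: int  # diploid individuals genotyped

    def __post_init__(self):
        if self.founder_size > self.census_size:
            raise ValueError(f"{self.name}: founder_size must be <= census_size")
        if self.sample_size > self.census_size:
            raise ValueError(f"{self.name}: sample_size must be <= census_size")


@dataclass
class FounderChainConfig:
    """Study-level configuration for the serial-founder generator."""

    chain: list[ChainStep]
    n_loci: int = 11
    n_ancestral_alleles: int = 8
    dirichlet_concentration: float = 1.0
    ladder_start: int = 160
    motif_length: int = 4
    ladder_slots: int = 12  # size ladder extent; mutation reflects at bounds
    mutation_rate: float = 5e-4  # per copy per generation, stepwise +-1 repeat
    missing_rate: float = 0.0
    # geography: chain positions along an equatorial transect
    spacing_km: float = 500.0
    extra_gap_km: dict[str, float] = field(default_factory=dict)
    # songs / hosts
    n_species: int = 18
    assemblage_window: int = 3
    assemblage_turnover: int = 2  # species replaced per chain step
    # mtDNA
    coi_length: int = 1111
    coi_theta: float = 6.0
    coi_sample_size: int = 20

    def __post_init__(self):
        if self.n_ancestral_alleles > self.ladder_slots:
            raise ValueError("ladder_slots must hold all ancestral alleles")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet concentration must be positive")

    def allele_size(self, slot: int) -> int:
        return self.ladder_start + self.motif_length * slot

    @classmethod
    def from_yaml(cls, path) -> "FounderChainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["chain"] = [ChainStep(**s) for s in raw["chain"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic bundle."""

    seed: int
    founder_events: list[tuple[str, str | None]]  # (population, source)
    allele_frequencies: dict  # pop -> locus -> {size: freq}
    expected_h_trajectory: dict  # pop -> mean expected heterozygosity
    haplotype_frequencies: dict | None = None
    song_parameters: dict | None = None
    effect_sizes: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _mutate_counts(counts: np.ndarray, mu: float, rng) -> np.ndarray:
    """Stepwise +-1-slot mutation on a count vector, reflecting at bounds."""
    if mu == 0:
        return counts
    k = counts.size
    out = counts.copy()
    mutants = rng.binomial(counts, mu)
    up = rng.binomial(mutants, 0.5)
    down = mutants - up
    out -= mutants
    for s in range(k):
        if up[s]:
            out[min(s + 1, k - 1) if s + 1 < k else s - 1] += up[s]
        if down[s]:
            out[s - 1 if s > 0 else s + 1] += down[s]
    return out


def simulate_genotypes(
    cfg: FounderChainConfig, seed: int
) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate the microsatellite component of a serial-founder study.

    Ancestral allele frequencies per locus are a single symmetric-Dirichlet
    draw over contiguous ladder slots.  Each chain step draws ``2 N_f``
    founder copies from its source's current frequencies, drifts ``g``
    Wright-Fisher generations at census size with stepwise mutation, then
    samples ``n`` diploids under Hardy-Weinberg (copies iid from the final
    frequencies, paired at random).
    """
    rng = np.random.default_rng(seed)
    L, K, S = cfg.n_loci, cfg.n_ancestral_alleles, cfg.ladder_slots
    offset = (S - K) // 2  # ancestral alleles sit mid-ladder
    ancestral = np.zeros((L, S))
    for l in range(L):
        ancestral[l, offset : offset + K] = rng.dirichlet(
            [cfg.dirichlet_concentration] * K
        )

    pop_freqs: dict[str, np.ndarray] = {}
    events: list[tuple[str, str | None]] = []
    source_freq = ancestral
    source_name: str | None = None
    for step in cfg.chain:
        freq = np.empty_like(source_freq)
        for l in range(L):
            counts = rng.multinomial(2 * step.founder_size, source_freq[l])
            # expand the founder pool to census size, then drift
            for _ in range(step.generations):
                counts = rng.multinomial(
                    2 * step.census_size, counts / counts.sum()
                )
                counts = _mutate_counts(counts, cfg.mutation_rate, rng)
            freq[l] = counts / counts.sum()
        pop_freqs[step.name] = freq
        events.append((step.name, source_name))
        source_freq, source_name = freq, step.name

    individuals: list[str] = []
    populations: dict[str, str] = {}
    blocks = []
    sizes = np.array([cfg.allele_size(s) for s in range(S)], dtype=np.int64)
    for step in cfg.chain:
        freq = pop_freqs[step.name]
        n = step.sample_size
        block = np.empty((n, L, 2), dtype=np.int64)
        for l in range(L):
            slots = rng.choice(S, size=2 * n, p=freq[l])
            block[:, l, :] = sizes[slots].reshape(n, 2)
        blocks.append(block)
        for i in range(n):
            ind = f"{step.name}_{i + 1:03d}"
            individuals.append(ind)
            populations[ind] = step.name
    calls = np.concatenate(blocks, axis=0)
    if cfg.missing_rate > 0:
        mask = rng.random((calls.shape[0], L)) < cfg.missing_rate
        calls[mask] = MISSING

    loci = [
        LocusInfo(name=f"L{l + 1:02d}", motif_length=cfg.motif_length)
        for l in range(L)
    ]
    ds = GenotypeDataset(individuals, populations, loci, calls)

    truth_freqs = {
        pop: {
            f"L{l + 1:02d}": {
                str(cfg.allele_size(s)): float(f[l, s])
                for s in range(S)
                if f[l, s] > 0
            }
            for l in range(L)
        }
        for pop, f in pop_freqs.items()
    }
    h_traj = {
        pop: float(np.mean([1.0 - np.sum(f[l] ** 2) for l in range(L)]))
        for pop, f in pop_freqs.items()
    }
    truth = TruthRecord(
        seed=seed,
        founder_events=events,
        allele_frequencies=truth_freqs,
        expected_h_trajectory=h_traj,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# COI
# ---------------------------------------------------------------------------

BASES = np.array(list("ACGT"))


def _apply_mutations(seq: np.ndarray, n_mut: int, rng) -> np.ndarray:
    """Jukes-Cantor: each mutation hits a uniform site and picks one of the
    three other bases."""
    out = seq.copy()
    for _ in range(n_mut):
        site = rng.integers(out.size)
        out[site] = (out[site] + 1 + rng.integers(3)) % 4
    return out


def simulate_coi(
    n_seq: int,
    length: int = 1111,
    genealogy: str = "star",
    theta: float = 4.0,
    seed: int | None = None,
    population: str = "Pop",
) -> SequenceAlignment:
    """Simulate an aligned sequence sample under a star or coalescent
    genealogy with Jukes-Cantor substitution.

    Star mode: each tip sits on an independent branch carrying
    ``Poisson(theta / 2)`` mutations, so expected pairwise differences are
    ``theta`` (before homoplasy).  Coalescent mode: a standard n-coalescent
    with branch mutations at rate ``theta / 2`` per unit coalescent time,
    giving Watterson's ``E[S] = theta * sum 1/i``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    root = rng.integers(4, size=length)
    seqs: list[np.ndarray] = []
    if genealogy == "star":
        for _ in range(n_seq):
            n_mut = rng.poisson(theta / 2)
            seqs.append(_apply_mutations(root, n_mut, rng))
    elif genealogy == "coalescent":
        lineages = {i: ([i], 0.0) for i in range(n_seq)}  # id -> (tips, len)
        nodes = {i: root for i in range(n_seq)}
        branch_len = {i: 0.0 for i in range(n_seq)}
        active = list(range(n_seq))
        parent_of: dict[int, int] = {}
        next_id = n_seq
        while len(active) > 1:
            k = len(active)
            t = rng.exponential(2.0 / (k * (k - 1)))
            for a in active:
                branch_len[a] += t
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            parent_of[a] = parent_of[b] = next_id
            active = [x for x in active if x not in (a, b)] + [next_id]
            branch_len[next_id] = 0.0
            next_id += 1
        # walk from root down, mutating along each branch
        seq_of = {active[0]: root}
        children: dict[int, list[int]] = {}
        for c, p in parent_of.items():
            children.setdefault(p, []).append(c)
        stack = [active[0]]
        while stack:
            node = stack.pop()
            for c in children.get(node, []):
                n_mut = rng.poisson(theta / 2 * branch_len[c])
                seq_of[c] = _apply_mutations(seq_of[node], n_mut, rng)
                stack.append(c)
        seqs = [seq_of[i] for i in range(n_seq)]
    else:
        raise ValueError("genealogy must be 'star' or 'coalescent'")
    records = {
        f"{population}_{i + 1:03d}": (population, "".join(BASES[s]))
        for i, s in enumerate(seqs)
    }
    return SequenceAlignment(records, length)


def _simulate_coi_chain(
    cfg: FounderChainConfig, rng
) -> tuple[SequenceAlignment, dict]:
    """COI sample for every chain population: an ancestral haplotype pool
    whose frequencies drift along the chain as a single haploid locus."""
    n_hap = max(4, cfg.n_ancestral_alleles)
    pool_aln = simulate_coi(
        n_hap,
        length=cfg.coi_length,
        genealogy="star",
        theta=cfg.coi_theta,
        seed=int(rng.integers(2**31)),
    )
    haplotypes = [seq for _pop, seq in pool_aln.records.values()]
    freq = rng.dirichlet([cfg.dirichlet_concentration] * n_hap)
    records: dict[str, tuple[str, str]] = {}
    hap_freqs: dict[str, dict[str, float]] = {}
    for step in cfg.chain:
        counts = rng.multinomial(step.founder_size, freq)
        for _ in range(step.generations):
            counts = rng.multinomial(step.census_size, counts / counts.sum())
        freq = counts / counts.sum()
        hap_freqs[step.name] = {f"hap{h + 1}": float(freq[h]) for h in range(n_hap)}
        n = min(cfg.coi_sample_size, step.sample_size)
        draws = rng.choice(n_hap, size=n, p=freq)
        for i, h in enumerate(draws):
            rid = f"{step.name}_{i + 1:03d}"
            records[rid] = (step.name, haplotypes[h])
    return SequenceAlignment(records, cfg.coi_length), hap_freqs


# ---------------------------------------------------------------------------
# songs and assemblages
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_LAWS = {
    "dominant_freq": (4.5, 0.5),
    "pulse_rate": (45.0, 22.0),
    "pulses_per_unit": (3.0, 1.2),  # lognormal: (mean, sd) of ln value
    "duty_cycle": (0.5, 0.2),
    "song_type_probs": (0.5, 0.25, 0.15, 0.1),
    "chirps_per_trill": (12.0, 8.0),
    "intro_pulses_per_trill": (7.0, 2.0),
    "intro_pulse_rate": (14.0, 4.0),
}


def simulate_songs(
    n_species: int, feature_laws: dict | None = None, seed: int | None = None
) -> list[SongRecord]:
    """Draw species song records from per-feature Gaussian laws (categorical
    for song type); conditional fields are generated only where the drawn
    song type has them."""
    laws = dict(DEFAULT_FEATURE_LAWS)
    if feature_laws:
        laws.update(feature_laws)
    rng = np.random.default_rng(seed)

    def pos(mean, sd, floor=1e-3):
        return max(float(rng.normal(mean, sd)), floor)

    records = []
    for i in range(n_species):
        st = SongType(int(rng.choice(4, p=np.asarray(laws["song_type_probs"]))))
        stutter = st in (SongType.STUTTER_TRILL, SongType.COMPLEX_STUTTER_TRILL)
        records.append(
            SongRecord(
                species=f"species_{i + 1:02d}",
                song_type=st,
                dominant_freq=pos(*laws["dominant_freq"]),
                pulse_rate=pos(*laws["pulse_rate"]),
                pulses_per_unit=float(np.exp(rng.normal(*laws["pulses_per_unit"]))),
                duty_cycle=float(np.clip(rng.normal(*laws["duty_cycle"]), 0.01, 0.99)),
                chirps_per_trill=pos(*laws["chirps_per_trill"]) if stutter else None,
                intro_pulses_per_trill=(
                    pos(*laws["intro_pulses_per_trill"])
                    if st is SongType.COMPLEX_STUTTER_TRILL
                    else None
                ),
                intro_pulse_rate=(
                    pos(*laws["intro_pulse_rate"])
                    if st is SongType.COMPLEX_STUTTER_TRILL
                    else None
                ),
            )
        )
    return records


def _chain_assemblages(cfg: FounderChainConfig, species: list[str]) -> list[HostAssemblage]:
    """Host assemblages sliding along the species list with the chain."""
    w, step = cfg.assemblage_window, cfg.assemblage_turnover
    out = []
    for i, pop in enumerate(cfg.chain):
        start = min(i * step, max(len(species) - w, 0))
        common = species[start : start + w]
        lo, hi = max(start - 1, 0), min(start + w + 1, len(species))
        out.append(HostAssemblage(pop.name, common, species[lo:hi]))
    return out


def _chain_coordinates(cfg: FounderChainConfig) -> dict[str, tuple[float, float]]:
    """Equatorial transect positions: fixed spacing plus optional extra gaps
    (e.g. an ocean crossing before the island populations)."""
    coords = {}
    lon = 0.0
    for i, step in enumerate(cfg.chain):
        if i > 0:
            lon += (cfg.spacing_km + cfg.extra_gap_km.get(step.name, 0.0)) / KM_PER_DEGREE
        coords[step.name] = (0.0, lon)
    return coords


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    genotypes: GenotypeDataset
    alignment: SequenceAlignment
    songs: list[SongRecord]
    assemblages: list[HostAssemblage]
    coordinates: dict[str, tuple[float, float]]
    truth: TruthRecord


def simulate_study(
    cfg: FounderChainConfig, seed: int, out_dir: str | Path | None = None
) -> StudyBundle:
    """Generate a complete synthetic study bundle (and optionally write it
    in the pipeline's standard input formats)."""
    rng = np.random.default_rng(seed)
    ds, truth = simulate_genotypes(cfg, int(rng.integers(2**31)))
    aln, hap_freqs = _simulate_coi_chain(cfg, rng)
    songs = simulate_songs(cfg.n_species, seed=int(rng.integers(2**31)))
    assemblages = _chain_assemblages(cfg, [r.species for r in songs])
    coords = _chain_coordinates(cfg)
    truth.haplotype_frequencies = hap_freqs
    truth.song_parameters = {"laws": {k: list(np.atleast_1d(v)) for k, v in DEFAULT_FEATURE_LAWS.items()}}
    truth.effect_sizes = {
        "spacing_km": cfg.spacing_km,
        "extra_gap_km": dict(cfg.extra_gap_km),
        "assemblage_turnover": cfg.assemblage_turnover,
        "founder_sizes": {s.name: s.founder_size for s in cfg.chain},
    }
    bundle = StudyBundle(ds, aln, songs, assemblages, coords, truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(bundle.genotypes, out / "genotypes.tsv")
    write_alignment(bundle.alignment, out / "coi.fasta")
    with open(out / "songs.tsv", "w") as fh:
        cols = [
            "species", "song_type", "dominant_freq", "pulse_rate",
            "pulses_per_unit", "duty_cycle", "chirps_per_trill",
            "intro_pulses_per_trill", "intro_pulse_rate",
        ]
        fh.write("\t".join(cols) + "\n")
        for r in bundle.songs:
            vals = [
                r.species,
                r.song_type.name.replace("_", " ").lower(),
                f"{r.dominant_freq:.6g}", f"{r.pulse_rate:.6g}",
                f"{r.pulses_per_unit:.6g}", f"{r.duty_cycle:.6g}",
                "" if r.chirps_per_trill is None else f"{r.chirps_per_trill:.6g}",
                "" if r.intro_pulses_per_trill is None else f"{r.intro_pulses_per_trill:.6g}",
                "" if r.intro_pulse_rate is None else f"{r.intro_pulse_rate:.6g}",
            ]
            fh.write("\t".join(vals) + "\n")
    with open(out / "assemblages.tsv", "w") as fh:
        fh.write("population\tcommon_hosts\tall_hosts\n")
        for a in bundle.assemblages:
            fh.write(
                f"{a.population}\t{';'.join(a.common_hosts)}\t{';'.join(a.all_hosts)}\n"
            )
    with open(out / "coordinates.tsv", "w") as fh:
        fh.write("population\tlat\tlon\n")
        for pop, (lat, lon) in bundle.coordinates.items():
            fh.write(f"{pop}\t{lat:.6f}\t{lon:.6f}\n")
    bundle.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

def default_scenario() -> FounderChainConfig:
    """Nine-population serial-founder chain mirroring the study system's
    direction of summary gradients: a diverse Gulf-coast ancestral range,
    progressively founded western populations, then severe island
    bottlenecks after an ocean gap."""
    chain = [
        ChainStep("Florida", 500, 10, 500, 40),
        ChainStep("Texas", 200, 10, 500, 35),
        ChainStep("Oaxaca", 150, 10, 500, 13),
        ChainStep("Sonora", 120, 10, 500, 17),
        ChainStep("Arizona", 100, 10, 500, 57),
        ChainStep("California", 30, 10, 300, 32),
        ChainStep("Oahu", 6, 10, 200, 28),
        ChainStep("Kauai", 8, 10, 200, 20),
        ChainStep("Hilo", 4, 10, 200, 32),
    ]
    return FounderChainConfig(
        chain=chain, extra_gap_km={"Oahu": 3500.0}
    )


def strong_ibd_scenario() -> FounderChainConfig:
    """Pronounced isolation-by-distance regime: smaller founder groups and
    longer drift at every mainland step, so genetic distance accumulates
    steadily along the transect."""
    chain = [
        ChainStep("P1", 300, 15, 300, 30),
        ChainStep("P2", 50, 15, 200, 30),
        ChainStep("P3", 40, 15, 200, 30),
        ChainStep("P4", 35, 15, 200, 30),
        ChainStep("P5", 30, 15, 200, 30),
        ChainStep("P6", 25, 15, 200, 30),
        ChainStep("P7", 20, 15, 200, 30),
        ChainStep("P8", 15, 15, 200, 30),
        ChainStep("P9", 12, 15, 200, 30),
    ]
    return FounderChainConfig(chain=chain)
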