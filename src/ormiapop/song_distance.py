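"""Host cricket song feature encoding and acoustic distance matrices.

Each confirmed host species' calling song is encoded as a fixed-length
feature vector: dominant frequency (kHz), pulse rate (pulses/s), ln pulses
per chirp-or-trill, pulse duty cycle, a song-type code, and the trill-
architecture variables that only apply to (complex) stutter-trillers, which
are zero-filled where inapplicable so that one rectangular matrix — and
hence a plain Euclidean distance — is defined for every species pair.
Columns are z-scored (sample SD, n-1) before distances are taken.

Fly populations parasitise assemblages of host species, so species-level
distances are aggregated to population level three ways: mean over common
hosts (``avg_common``), minimum over common hosts (``min_common``), and
minimum over all known hosts (``min_any``).  Populations sharing a host get
zero under the minimum methods by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrices import DistanceMatrix

__all__ = [
    "SongType",
    "SongRecord",
    "SongFeatureMatrix",
    "HostAssemblage",
    "encode_song_features",
    "species_song_distance",
    "assemblage_stat",
    "population_song_distance",
    "read_song_table",
    "read_assemblages",
]


class SongType(IntEnum):
    """Ordinal song-architecture code, from simplest to most structured."""

    CHIRP = 0
    TRILL = 1
    STUTTER_TRILL = 2
    COMPLEX_STUTTER_TRILL = 3

    @classmethod
    def parse(cls, text: str) -> "SongType":
        key = text.strip().lower().replace("-", " ").replace("_", " ")
        table = {
            "chirp": cls.CHIRP,
            "fast chirp": cls.CHIRP,
            "trill": cls.TRILL,
            "stutter trill": cls.STUTTER_TRILL,
            "complex stutter trill": cls.COMPLEX_STUTTER_TRILL,
        }
        if key not in table:
            raise ValueError(f"unknown song type {text!r}")
        return table[key]


@dataclass
class SongRecord:
    """One host species' song. Conditional fields apply only to the song
    architectures that have them (chirps_per_trill for stutter-trillers,
    introductory-part fields for complex stutter-trillers)."""

    species: str
    song_type: SongType
    dominant_freq: float  # kHz
    pulse_rate: float  # pulses/s
    pulses_per_unit: float  # pulses per chirp or trill
    duty_cycle: float  # fraction of unit time with sound on
    chirps_per_trill: float | None = None
    intro_pulses_per_trill: float | None = None
    intro_pulse_rate: float | None = None

    def __post_init__(self):
        if self.dominant_freq <= 0:
            raise ValueError(f"{self.species}: dominant_freq must be positive")
        if self.pulse_rate <= 0:
            raise ValueError(f"{self.species}: pulse_rate must be positive")
        if self.pulses_per_unit <= 0:
            raise ValueError(
                f"{self.species}: pulses_per_unit must be positive (ln-transform)"
            )
        stutter = self.song_type in (
            SongType.STUTTER_TRILL,
            SongType.COMPLEX_STUTTER_TRILL,
        )
        if stutter and self.chirps_per_trill is None:
            raise ValueError(f"{self.species}: stutter-triller needs chirps_per_trill")
        if not stutter and self.chirps_per_trill is not None:
            raise ValueError(f"{self.species}: chirps_per_trill not applicable")
        complex_ = self.song_type is SongType.COMPLEX_STUTTER_TRILL
        has_intro = (
            self.intro_pulses_per_trill is not None
            or self.intro_pulse_rate is not None
        )
        if complex_ and (
            self.intro_pulses_per_trill is None or self.intro_pulse_rate is None
        ):
            raise ValueError(f"{self.species}: complex song needs both intro fields")
        if not complex_ and has_intro:
            raise ValueError(f"{self.species}: intro fields not applicable")


FEATURE_NAMES = [
    "dominant_freq",
    "pulse_rate",
    "ln_pulses_per_unit",
    "duty_cycle",
    "song_type_code",
    "chirps_per_trill",
    "intro_pulses_per_trill",
    "intro_pulse_rate",
]


@dataclass
class SongFeatureMatrix:
    species: list[str]
    feature_names: list[str]
    raw: pd.DataFrame
    zscored: pd.DataFrame
    dropped_constant: list[str]


def encode_song_features(
    records: Sequence[SongRecord], one_hot_song_type: bool = False
) -> SongFeatureMatrix:
    """Species x feature matrix, raw and z-scored.

    Inapplicable conditional features are zero-filled before z-scoring;
    columns with zero variance are flagged and dropped from the z-scored
    matrix.  ``one_hot_song_type`` swaps the ordinal song-type code for
    indicator columns (a sensitivity mode).
    """
    if len(records) < 2:
        raise ValueError("need >= 2 species to z-score features")
    names = [r.species for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species in song records")
    rows = []
    for r in records:
        row = {
            "dominant_freq": r.dominant_freq,
            "pulse_rate": r.pulse_rate,
            "ln_pulses_per_unit": float(np.log(r.pulses_per_unit)),
            "duty_cycle": r.duty_cycle,
            "chirps_per_trill": r.chirps_per_trill or 0.0,
            "intro_pulses_per_trill": r.intro_pulses_per_trill or 0.0,
            "intro_pulse_rate": r.intro_pulse_rate or 0.0,
        }
        if one_hot_song_type:
            for st in SongType:
                row[f"song_type_{st.name.lower()}"] = float(r.song_type is st)
        else:
            row["song_type_code"] = float(int(r.song_type))
        rows.append(row)
    raw = pd.DataFrame(rows, index=names)
    if not one_hot_song_type:
        raw = raw[FEATURE_NAMES]
    sd = raw.std(ddof=1)
    constant = list(sd.index[sd == 0])
    keep = [c for c in raw.columns if c not in constant]
    z = (raw[keep] - raw[keep].mean()) / raw[keep].std(ddof=1)
    return SongFeatureMatrix(names, list(raw.columns), raw, z, constant)


def species_song_distance(fm: SongFeatureMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between z-scored song feature vectors."""
    d = squareform(pdist(fm.zscored.to_numpy(), metric="euclidean"))
    return DistanceMatrix(fm.species, d, name="song_distance")


def assemblage_stat(
    dm: DistanceMatrix, focal: str, others: Iterable[str], stat: str = "mean"
) -> float:
    """Mean or min distance from a focal species to a set of other species."""
    others = list(others)
    if not others:
        raise ValueError("empty species set")
    vals = [dm[focal, s] for s in others]
    if stat == "mean":
        return float(np.mean(vals))
    if stat == "min":
        return float(np.min(vals))
    raise ValueError(f"stat must be 'mean' or 'min', got {stat!r}")


@dataclass
class HostAssemblage:
    """The cricket hosts a fly population uses: the regularly used subset
    (``common_hosts``) and every confirmed host (``all_hosts``)."""

    population: str
    common_hosts: list[str]
    all_hosts: list[str]

    def __post_init__(self):
        if not self.common_hosts:
            raise ValueError(f"{self.population}: common_hosts must be non-empty")
        missing = set(self.common_hosts) - set(self.all_hosts)
        if missing:
            self.all_hosts = self.all_hosts + sorted(missing)


METHODS = ("avg_common", "min_common", "min_any")


def population_song_distance(
    dm: DistanceMatrix,
    assemblages: Sequence[HostAssemblage],
    method: str = "avg_common",
) -> DistanceMatrix:
    """Aggregate species song distances to fly-population song distances.

    For populations P and Q the entry is the mean (``avg_common``) or the
    minimum (``min_common``, ``min_any``) of ``d(s, t)`` over all cross
    pairs of hosts ``s`` of P and ``t`` of Q; common-host methods use the
    regularly-used hosts, ``min_any`` uses every known host.  A shared host
    contributes a zero-distance pair, so populations sharing a host score 0
    under the minimum methods.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    known = set(dm.labels)
    for a in assemblages:
        unknown = set(a.all_hosts) - known
        if unknown:
            raise ValueError(
                f"assemblage {a.population!r} references species absent from "
                f"the song distance matrix: {sorted(unknown)}"
            )
    hosts = {
        a.population: (a.all_hosts if method == "min_any" else a.common_hosts)
        for a in assemblages
    }
    pops = [a.population for a in assemblages]
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = [dm[s, t] for s in hosts[pops[i]] for t in hosts[pops[j]]]
            m[i, j] = m[j, i] = (
                float(np.mean(vals)) if method == "avg_common" else float(np.min(vals))
            )
    return DistanceMatrix(pops, m, name=f"song_{method}")


# ---------------------------------------------------------------------------
# delimited IO
# ---------------------------------------------------------------------------

def read_song_table(path, sep: str = "\t") -> list[SongRecord]:
    """Read a song feature table (one row per species; blank = inapplicable)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    records = []
    for _, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        records.append(
            SongRecord(
                species=str(row["species"]),
                song_type=SongType.parse(str(row["song_type"])),
                dominant_freq=float(row["dominant_freq"]),
                pulse_rate=float(row["pulse_rate"]),
                pulses_per_unit=float(row["pulses_per_unit"]),
                duty_cycle=float(row["duty_cycle"]),
                chirps_per_trill=opt("chirps_per_trill"),
                intro_pulses_per_trill=opt("intro_pulses_per_trill"),
                intro_pulse_rate=opt("intro_pulse_rate"),
            )
        )
    return records


def read_assemblages(path, sep: str = "\t") -> list[HostAssemblage]:
    """Read a host assemblage table: population, common_hosts, all_hosts
    (host lists semicolon-separated)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    out = []
    for _, row in df.iterrows():
        common = [s.strip() for s in str(row["common_hosts"]).split(";") if s.strip()]
        all_h = [s.strip() for s in str(row["all_hosts"]).split(";") if s.strip()]
        out.append(HostAssemblage(str(row["population"]), common, all_h))
    return out
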