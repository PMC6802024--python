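"""Packaged reference tables from the fly biogeography study system.

These are the desk-scale inputs printed in the study's tables: the pairwise
Fst / Nei distance matrices (full 11-locus panel and the reduced 8-locus
panel excluding the three HWE-deviating loci), the per-population
heterozygosity summary, the confirmed host-species song features (printed
ranges resolved to midpoints; the duty-cycle column is a synthetic proxy —
see the data file header), the per-population host assemblages, and
approximate collection-site coordinates.  The full individual-level
genotype and sequence deposits are external downloads and are not bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrices import DistanceMatrix
from .song_distance import HostAssemblage, SongRecord, read_assemblages, read_song_table

POPULATIONS = [
    "Kauai", "Oahu", "Hilo", "California", "Arizona",
    "Sonora", "Oaxaca", "Texas", "Florida",
]
HAWAII = ["Kauai", "Oahu", "Hilo"]
MAINLAND = [p for p in POPULATIONS if p not in HAWAII]
HWE_DEVIATING_LOCI = ["Oo022", "Oo024", "Oo035"]

__all__ = [
    "POPULATIONS", "HAWAII", "MAINLAND", "HWE_DEVIATING_LOCI",
    "nei_matrix", "fst_matrix", "population_summary_table",
    "host_songs", "host_assemblages", "population_coordinates",
]


def _path(name: str):
    return resources.files("ormiapop.data").joinpath(name)


def nei_matrix(loci: int = 11) -> DistanceMatrix:
    """Printed pairwise Nei standard genetic distances (11- or 8-locus)."""
    if loci not in (11, 8):
        raise ValueError("loci must be 11 or 8")
    with resources.as_file(_path(f"nei_{loci}locus.tsv")) as p:
        return DistanceMatrix.read_tsv(p)


def fst_matrix(loci: int = 11) -> DistanceMatrix:
    """Printed pairwise Weir-Cockerham Fst (11- or 8-locus)."""
    if loci not in (11, 8):
        raise ValueError("loci must be 11 or 8")
    with resources.as_file(_path(f"fst_{loci}locus.tsv")) as p:
        return DistanceMatrix.read_tsv(p, allow_negative=True)


def population_summary_table() -> pd.DataFrame:
    """Reported per-population sample sizes and heterozygosities."""
    with resources.as_file(_path("population_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", index_col="population")


def host_songs() -> list[SongRecord]:
    """Song features of the 18 confirmed host species (range midpoints)."""
    with resources.as_file(_path("host_songs.tsv")) as p:
        return read_song_table(p)


def host_assemblages() -> list[HostAssemblage]:
    """Common and known host assemblages of the nine fly populations."""
    with resources.as_file(_path("host_assemblages.tsv")) as p:
        return read_assemblages(p)


def population_coordinates() -> dict[str, tuple[float, float]]:
    """Approximate collection-site coordinates (lat, lon degrees)."""
    with resources.as_file(_path("population_coordinates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {
        str(r["population"]): (float(r["lat"]), float(r["lon"]))
        for _, r in df.iterrows()
    }
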