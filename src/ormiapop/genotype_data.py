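"""Diploid microsatellite genotype tables: reading, validation, QC filters.

The genotype table is a delimited text file with one row per individual::

    id      population  Oo002_1  Oo002_2  Oo007_1  Oo007_2 ...
    FL_01   Florida     191      195      286      289

Allele calls are fragment sizes in base pairs (positive integers); missing
calls use a sentinel (``NA`` or ``0`` by default, configurable).  Optional
comment lines ``# motif <locus> <bp>`` carry the repeat-motif length used by
the Garza–Williamson M statistic.

Quality control mirrors standard microsatellite practice: loci whose missing
fraction strictly exceeds a cutoff (default 25%) are dropped first, then
individuals still missing data at more than a fixed number of loci (default
2, i.e. individuals with >= 3 missing loci go) are removed.  The locus filter
runs first because a bad locus should not count against an individual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
DEFAULT_SENTINELS = frozenset({"NA", "0", "", "NaN", "nan", "-9"})

__all__ = [
    "LocusInfo",
    "GenotypeDataset",
    "read_genotypes",
    "read_genotypes_two_row",
    "write_genotypes",
    "filter_loci_by_missingness",
    "filter_individuals_by_missing_loci",
    "missing_fraction",
    "pool_populations",
    "MISSING",
]


@dataclass(frozen=True)
class LocusInfo:
    """Microsatellite locus metadata (name, repeat motif length in bp)."""

    name: str
    motif_length: int = 1
    reference_size: int | None = None

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name}: motif_length must be >= 1")


@dataclass
class GenotypeDataset:
    """Allele-size calls for individuals x loci with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2); each entry is an allele
    fragment size in bp, or :data:`MISSING`.  The two alleles of a genotype
    are unordered and stored sorted.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[LocusInfo]
    calls: np.ndarray

    def __post_init__(self):
        if len(set(self.individuals)) != len(self.individuals):
            dupes = {i for i in self.individuals if self.individuals.count(i) > 1}
            raise ValueError(f"duplicate individual IDs: {sorted(dupes)}")
        missing_pop = [i for i in self.individuals if i not in self.populations]
        if missing_pop:
            raise ValueError(f"individuals without population label: {missing_pop}")
        self.calls = np.asarray(self.calls, dtype=np.int64)
        expect = (len(self.individuals), len(self.loci), 2)
        if self.calls.shape != expect:
            raise ValueError(f"calls shape {self.calls.shape} != {expect}")
        # canonicalise unordered pairs; a half-missing genotype is missing
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        self._validate_motif_congruence()

    def _validate_motif_congruence(self):
        for j, locus in enumerate(self.loci):
            if locus.motif_length <= 1:
                continue
            sizes = self.calls[:, j, :]
            sizes = np.unique(sizes[sizes != MISSING])
            if sizes.size > 1 and np.unique(sizes % locus.motif_length).size > 1:
                warnings.warn(
                    f"locus {locus.name}: allele sizes not mutually congruent "
                    f"modulo motif length {locus.motif_length}",
                    stacklevel=3,
                )

    # -- derived views -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            p = self.populations[ind]
            if p not in seen:
                seen.append(p)
        return seen

    def population_of(self, pop: str) -> np.ndarray:
        """Row indices of the individuals in a population."""
        return np.array(
            [k for k, ind in enumerate(self.individuals) if self.populations[ind] == pop],
            dtype=int,
        )

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask of missing genotypes."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, individuals=None, loci=None) -> "GenotypeDataset":
        inds = list(individuals) if individuals is not None else list(self.individuals)
        locs = list(loci) if loci is not None else self.locus_names
        row = [self.individuals.index(i) for i in inds]
        col = [self.locus_names.index(l) for l in locs]
        return GenotypeDataset(
            individuals=inds,
            populations={i: self.populations[i] for i in inds},
            loci=[self.loci[c] for c in col],
            calls=self.calls[np.ix_(row, col)],
        )

    def drop_loci(self, names: Sequence[str]) -> "GenotypeDataset":
        keep = [l for l in self.locus_names if l not in set(names)]
        return self.subset(loci=keep)


def _parse_motif_comments(path: Path) -> dict[str, int]:
    motifs: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 3 and parts[0] == "motif":
                motifs[parts[1]] = int(parts[2])
    return motifs


def read_genotypes(
    path,
    sep: str = "\t",
    missing_sentinels: frozenset[str] | set[str] = DEFAULT_SENTINELS,
    motifs: Mapping[str, int] | None = None,
) -> GenotypeDataset:
    """Read a one-row-per-individual genotype table.

    Columns: ``id``, ``population``, then two columns per locus named
    ``<locus>_1`` / ``<locus>_2``.  Motif lengths come from ``# motif`` header
    comments, overridden by the ``motifs`` argument.
    """
    path = Path(path)
    motif_map = _parse_motif_comments(path)
    if motifs:
        motif_map.update(motifs)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected id, population and >=1 locus pair")
    id_col, pop_col = df.columns[:2]
    locus_cols = list(df.columns[2:])
    if len(locus_cols) % 2:
        raise ValueError(f"{path}: odd number of allele columns")
    loci: list[LocusInfo] = []
    for k in range(0, len(locus_cols), 2):
        a, b = locus_cols[k], locus_cols[k + 1]
        name = a.rsplit("_", 1)[0]
        if b.rsplit("_", 1)[0] != name:
            raise ValueError(f"{path}: allele columns {a!r}/{b!r} not paired")
        loci.append(LocusInfo(name=name, motif_length=motif_map.get(name, 1)))

    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate individual IDs {dupes}")
    pops = dict(zip(ids, df[pop_col].astype(str)))

    calls = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int64)
    for j in range(len(loci)):
        for a_idx, col in enumerate(locus_cols[2 * j : 2 * j + 2]):
            for r, raw in enumerate(df[col]):
                raw = "" if pd.isna(raw) else str(raw).strip()
                if raw in missing_sentinels:
                    continue
                try:
                    size = int(float(raw)) if float(raw) == int(float(raw)) else None
                except ValueError:
                    raise ValueError(
                        f"{path}: row {r + 2} column {col!r}: "
                        f"unparseable allele call {raw!r}"
                    ) from None
                if size is None or size <= 0:
                    raise ValueError(
                        f"{path}: row {r + 2} column {col!r}: allele size {raw!r} "
                        "must be a positive integer fragment length in bp "
                        "(pre-bin fractional sizes before import)"
                    )
                calls[r, j, a_idx] = size

    ds = GenotypeDataset(ids, pops, loci, calls)
    logger.info(
        "read %s: %d individuals, %d loci, %.2f%% missing",
        path, ds.n_individuals, ds.n_loci, 100 * missing_fraction(ds),
    )
    return ds


def read_genotypes_two_row(
    path,
    sep: str = "\t",
    missing_sentinels=DEFAULT_SENTINELS,
    motifs: Mapping[str, int] | None = None,
) -> GenotypeDataset:
    """Importer for the two-rows-per-individual dialect (one allele per row)."""
    path = Path(path)
    motif_map = _parse_motif_comments(path)
    if motifs:
        motif_map.update(motifs)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    id_col, pop_col = df.columns[:2]
    locus_names = list(df.columns[2:])
    if len(df) % 2:
        raise ValueError(f"{path}: two-row dialect needs an even number of rows")
    loci = [LocusInfo(n, motif_map.get(n, 1)) for n in locus_names]
    ids, pops = [], {}
    calls = np.full((len(df) // 2, len(loci), 2), MISSING, dtype=np.int64)
    for r in range(0, len(df), 2):
        top, bot = df.iloc[r], df.iloc[r + 1]
        if top[id_col] != bot[id_col]:
            raise ValueError(f"{path}: rows {r + 2},{r + 3} have mismatched IDs")
        ind = str(top[id_col])
        if ind in pops:
            raise ValueError(f"{path}: duplicate individual ID {ind}")
        ids.append(ind)
        pops[ind] = str(top[pop_col])
        for j, name in enumerate(locus_names):
            for a_idx, row in enumerate((top, bot)):
                raw = "" if pd.isna(row[name]) else str(row[name]).strip()
                if raw in missing_sentinels:
                    continue
                calls[r // 2, j, a_idx] = int(float(raw))
    return GenotypeDataset(ids, pops, loci, calls)


def write_genotypes(ds: GenotypeDataset, path, sep: str = "\t") -> None:
    """Write the one-row dialect; round-trips through :func:`read_genotypes`."""
    path = Path(path)
    with open(path, "w") as fh:
        for locus in ds.loci:
            if locus.motif_length > 1:
                fh.write(f"# motif {locus.name} {locus.motif_length}\n")
        cols = ["id", "population"]
        for l in ds.loci:
            cols += [f"{l.name}_1", f"{l.name}_2"]
        fh.write(sep.join(cols) + "\n")
        for r, ind in enumerate(ds.individuals):
            row = [ind, ds.populations[ind]]
            for j in range(ds.n_loci):
                for a in ds.calls[r, j]:
                    row.append("NA" if a == MISSING else str(int(a)))
            fh.write(sep.join(row) + "\n")


def missing_fraction(ds: GenotypeDataset) -> float:
    """Fraction of individual x locus genotypes that are missing."""
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("empty dataset")
    return float(ds.missing_mask().mean())


def filter_loci_by_missingness(
    ds: GenotypeDataset, max_missing: float = 0.25
) -> GenotypeDataset:
    """Drop loci whose missing fraction strictly exceeds ``max_missing``.

    A locus at exactly the cutoff is retained (strict ``>`` comparison).
    """
    if not (0 <= max_missing < 1):
        raise ValueError("max_missing must be in [0, 1)")
    frac = ds.missing_mask().mean(axis=0)
    keep = [l.name for l, f in zip(ds.loci, frac) if f <= max_missing]
    dropped = [l.name for l, f in zip(ds.loci, frac) if f > max_missing]
    if not keep:
        raise ValueError("all loci exceed the missingness cutoff")
    if dropped:
        logger.info("filter_loci_by_missingness: removed %s", dropped)
    return ds.subset(loci=keep)


def filter_individuals_by_missing_loci(
    ds: GenotypeDataset, max_missing_loci: int = 2
) -> GenotypeDataset:
    """Drop individuals missing data at more than ``max_missing_loci`` loci.

    With the default of 2, an individual missing at three or more loci is
    excluded.  Run after :func:`filter_loci_by_missingness` so discarded loci
    do not count against individuals.
    """
    n_missing = ds.missing_mask().sum(axis=1)
    keep = [i for i, m in zip(ds.individuals, n_missing) if m <= max_missing_loci]
    removed = [i for i in ds.individuals if i not in set(keep)]
    if removed:
        per_pop: dict[str, int] = {}
        for i in removed:
            per_pop[ds.populations[i]] = per_pop.get(ds.populations[i], 0) + 1
        logger.info(
            "filter_individuals_by_missing_loci: removed %d individuals %s",
            len(removed), per_pop,
        )
    out = ds.subset(individuals=keep)
    lost = set(ds.population_labels) - set(out.population_labels)
    for pop in sorted(lost):
        warnings.warn(f"population {pop} lost all individuals during filtering")
    return out


def pool_populations(
    ds: GenotypeDataset, pooling: Mapping[str, str]
) -> GenotypeDataset:
    """Relabel populations (e.g. pool the Hawaiian islands for HWE / M tests).

    ``pooling`` maps old labels to new ones; unmapped labels pass through.
    """
    new_pops = {i: pooling.get(p, p) for i, p in ds.populations.items()}
    return replace(ds, populations=new_pops, calls=ds.calls.copy())
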