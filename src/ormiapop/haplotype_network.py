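"""COI haplotype collapsing and minimum-spanning haplotype networks.

Aligned mitochondrial sequences are collapsed by exact identity (ambiguity
codes treated as literal symbols — wildcard matching of N against everything
is non-transitive and would make the haplotype count depend on input order).
The network is a minimum spanning tree on pairwise Hamming distances built
with a deterministic Kruskal (edges sorted by weight then lexicographic node
pair); equally good alternative connections are reported in ``alt_edges``
rather than emulating any randomized tie-breaking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrices import DistanceMatrix

IUPAC = set("ACGTURYSWKMBDHVN-")

__all__ = [
    "SequenceAlignment",
    "HaplotypeSet",
    "HaplotypeNetwork",
    "read_alignment",
    "write_alignment",
    "collapse_haplotypes",
    "pairwise_hamming",
    "build_msn",
    "haplotype_summaries",
]


@dataclass
class SequenceAlignment:
    """Equal-length uppercase sequences with a population label per record."""

    records: dict[str, tuple[str, str]]  # id -> (population, sequence)
    length: int

    def __post_init__(self):
        for rid, (_pop, seq) in self.records.items():
            if len(seq) != self.length:
                raise ValueError(
                    f"record {rid!r} has length {len(seq)}, alignment is {self.length}"
                )
            bad = set(seq) - IUPAC
            if bad:
                raise ValueError(f"record {rid!r}: non-IUPAC symbols {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for pop, _ in self.records.values():
            if pop not in seen:
                seen.append(pop)
        return seen


def read_alignment(
    path,
    population_regex: str = r"^([A-Za-z]+)",
    populations: Mapping[str, str] | None = None,
) -> SequenceAlignment:
    """Read a FASTA alignment; population from a header regex or sidecar map.

    The first capture group of ``population_regex`` applied to the record ID
    gives the population unless an explicit ``populations`` mapping is
    supplied.
    """
    pat = re.compile(population_regex)
    records: dict[str, tuple[str, str]] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in records:
            raise ValueError(f"{path}: duplicate record ID {rid!r}")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"{path}: record {rid!r} length {len(seq)} != {length} (ragged)"
            )
        if populations is not None:
            try:
                pop = populations[rid]
            except KeyError:
                raise ValueError(f"{path}: no population for record {rid!r}") from None
        else:
            m = pat.search(rid)
            if not m:
                raise ValueError(
                    f"{path}: cannot parse population from ID {rid!r} "
                    f"with regex {population_regex!r}"
                )
            pop = m.group(1)
        records[rid] = (pop, seq)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceAlignment(records, length)


def write_alignment(aln: SequenceAlignment, path) -> None:
    with open(Path(path), "w") as fh:
        for rid, (pop, seq) in aln.records.items():
            fh.write(f">{rid} pop={pop}\n{seq}\n")


@dataclass
class HaplotypeSet:
    """Unique haplotype sequences with per-population frequencies."""

    haplotypes: list[str]
    counts: pd.DataFrame  # haplotype index x population
    membership: dict[str, int]  # record id -> haplotype index

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequencies(self, pop: str) -> np.ndarray:
        col = self.counts[pop].to_numpy(dtype=float)
        return col / col.sum()


def collapse_haplotypes(
    aln: SequenceAlignment, drop_ambiguous_columns: bool = False
) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes, ordered by first seen.

    With ``drop_ambiguous_columns`` the columns containing any non-ACGT
    symbol are removed before collapsing (an alternative mode for datasets
    with scattered ambiguity calls); by default ambiguity codes are literal
    and distinguish haplotypes.
    """
    seqs = {rid: seq for rid, (_p, seq) in aln.records.items()}
    if drop_ambiguous_columns:
        cols = [
            c
            for c in range(aln.length)
            if all(seq[c] in "ACGT" for seq in seqs.values())
        ]
        seqs = {rid: "".join(seq[c] for c in cols) for rid, seq in seqs.items()}
    haplotypes: list[str] = []
    index: dict[str, int] = {}
    membership: dict[str, int] = {}
    pops = aln.population_labels()
    counts = np.zeros((0, len(pops)), dtype=int)
    pop_idx = {p: k for k, p in enumerate(pops)}
    rows: list[np.ndarray] = []
    for rid, (pop, _seq) in aln.records.items():
        seq = seqs[rid]
        if seq not in index:
            index[seq] = len(haplotypes)
            haplotypes.append(seq)
            rows.append(np.zeros(len(pops), dtype=int))
        h = index[seq]
        membership[rid] = h
        rows[h][pop_idx[pop]] += 1
    counts = pd.DataFrame(np.vstack(rows), columns=pops)
    return HaplotypeSet(haplotypes, counts, membership)


def pairwise_hamming(hs: HaplotypeSet, ignore_ambiguous: bool = False) -> DistanceMatrix:
    """Integer Hamming distances between haplotypes.

    With ``ignore_ambiguous`` a column is skipped for a pair when either
    member carries a non-ACGT symbol there; by default symbols are compared
    literally.
    """
    n = hs.n_haplotypes
    arr = np.array([list(h) for h in hs.haplotypes])
    m = np.zeros((n, n))
    for i in range(n):
        diff = arr[i] != arr[i + 1 :]
        if ignore_ambiguous and n > i + 1:
            ok_i = np.isin(arr[i], list("ACGT"))
            ok_j = np.isin(arr[i + 1 :], list("ACGT"))
            diff = diff & ok_i[None, :] & ok_j
        d = diff.sum(axis=1)
        m[i, i + 1 :] = d
        m[i + 1 :, i] = d
    labels = [f"H{k + 1}" for k in range(n)]
    return DistanceMatrix(labels, m, name="hamming")


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning haplotype network with alternative-edge annotations."""

    graph: nx.Graph
    alt_edges: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _u, _v, d in self.graph.edges(data=True)))


def build_msn(hs: HaplotypeSet, epsilon: int = 0) -> HaplotypeNetwork:
    """Minimum spanning tree over haplotype Hamming distances.

    Deterministic Kruskal: candidate edges sorted by (weight, i, j).  Non-tree
    edges whose weight is within ``epsilon`` of the heaviest edge on the tree
    path between their endpoints are reported as ``alt_edges`` (the equal-
    weight alternative connections a randomized MST could have chosen).
    """
    n = hs.n_haplotypes
    if n < 2:
        raise ValueError("need >= 2 haplotypes to build a network")
    dm = pairwise_hamming(hs)
    edges = sorted(
        ((int(dm.values[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    g = nx.Graph()
    totals = hs.counts.sum(axis=1)
    for k in range(n):
        g.add_node(
            k,
            frequency=int(totals.iloc[k]),
            populations={
                p: int(c) for p, c in hs.counts.iloc[k].items() if c > 0
            },
        )
    in_tree = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            g.add_edge(i, j, weight=w)
            in_tree.append((i, j))
    tree_set = {frozenset(e) for e in in_tree}
    alt: list[tuple[int, int, int]] = []
    for w, i, j in edges:
        if frozenset((i, j)) in tree_set:
            continue
        path = nx.shortest_path(g, i, j)
        path_max = max(
            g[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        if w <= path_max + epsilon:
            alt.append((i, j, w))
    return HaplotypeNetwork(g, alt)


def haplotype_summaries(hs: HaplotypeSet) -> dict:
    """Per-population haplotype counts, diversity, and sharing incidence.

    Haplotype (gene) diversity ``h = n/(n-1) * (1 - sum f_i^2)``; undefined
    (NaN, flagged) for populations with fewer than two sequences.  The
    shared-incidence matrix marks population pairs sharing >= 1 haplotype.
    """
    pops = list(hs.counts.columns)
    n_hap = (hs.counts > 0).sum(axis=0)
    n_seq = hs.counts.sum(axis=0)
    div = {}
    flagged = []
    for p in pops:
        n = int(n_seq[p])
        if n < 2:
            div[p] = float("nan")
            flagged.append(p)
            continue
        f = hs.frequencies(p)
        div[p] = n / (n - 1) * (1.0 - float(np.sum(f**2)))
    present = hs.counts.to_numpy() > 0
    shared = (present.T @ present) > 0
    np.fill_diagonal(shared, False)
    return {
        "n_sequences": n_seq.astype(int),
        "n_haplotypes": n_hap.astype(int),
        "diversity": pd.Series(div),
        "diversity_undefined": flagged,
        "shared_incidence": pd.DataFrame(shared, index=pops, columns=pops),
    }
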