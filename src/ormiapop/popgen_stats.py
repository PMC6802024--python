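"""Microsatellite population-genetic statistics computed from first principles.

Everything here operates on a filtered :class:`~ormiapop.genotype_data.
GenotypeDataset` and uses locus-specific non-missing sample sizes throughout.

Statistics
----------
* observed / expected heterozygosity (gene diversity ``1 - sum p^2``; the
  unbiased variant multiplies per-locus gene diversity by ``2n/(2n-1)``)
* rarefied allelic richness and rarefied private-allele counts
  (hypergeometric expectation over subsamples of ``g`` gene copies)
* pairwise Weir & Cockerham (1984) theta, from the a/b/c variance components
  evaluated per allele per locus on the two-population subset
* Nei (1972) standard genetic distance ``D = -ln I``
* Garza & Williamson (2001) ``M = k / (r + 1)`` with the allele-size range
  ``r`` expressed in repeat units
* Hardy-Weinberg tests: Monte-Carlo gamete re-pairing (heterozygote-count
  statistic, two-sided, +1-corrected p), with a full-enumeration exact test
  for tiny samples as an independent cross-check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotype_data import MISSING, GenotypeDataset
from .matrices import DistanceMatrix

__all__ = [
    "AlleleFrequencyTable",
    "PopGenSummary",
    "HWETestResult",
    "allele_frequencies",
    "heterozygosity",
    "rarefied_allelic_richness",
    "rarefied_private_alleles",
    "pairwise_fst_wc",
    "weir_cockerham_theta",
    "nei_distance",
    "garza_williamson_m",
    "hwe_permutation_test",
    "hwe_exact_enumeration",
    "population_summary",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per population x locus allele counts over non-missing gene copies.

    ``counts[pop][locus]`` maps allele size -> count of gene copies; a
    population unscored at a locus has no entry there.
    """

    populations: list[str]
    loci: list[str]
    counts: dict[str, dict[str, dict[int, int]]]

    def n_copies(self, pop: str, locus: str) -> int:
        return sum(self.counts[pop].get(locus, {}).values())

    def frequencies(self, pop: str, locus: str) -> dict[int, float]:
        c = self.counts[pop].get(locus, {})
        n = sum(c.values())
        return {a: k / n for a, k in c.items()} if n else {}

    def alleles(self, locus: str) -> list[int]:
        out: set[int] = set()
        for pop in self.populations:
            out.update(self.counts[pop].get(locus, {}))
        return sorted(out)


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Tally gene copies per population x locus, skipping missing genotypes."""
    counts: dict[str, dict[str, dict[int, int]]] = {}
    for pop in ds.population_labels:
        rows = ds.population_of(pop)
        counts[pop] = {}
        for j, locus in enumerate(ds.locus_names):
            sizes = ds.calls[rows, j, :].ravel()
            sizes = sizes[sizes != MISSING]
            if sizes.size == 0:
                continue  # flagged absent: no entry
            vals, n = np.unique(sizes, return_counts=True)
            counts[pop][locus] = {int(a): int(k) for a, k in zip(vals, n)}
    return AlleleFrequencyTable(ds.population_labels, ds.locus_names, counts)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class PopGenSummary:
    """Per-population summary statistics, averaged over loci."""

    population: str
    n_individuals: int
    h_obs: float
    h_exp: float
    h_exp_unbiased: float
    mean_alleles: float
    total_alleles: int
    rarefied_richness: float | None = None
    rarefied_private: float | None = None
    gw_m: float | None = None
    per_locus: pd.DataFrame | None = field(default=None, repr=False)


def heterozygosity(
    freqs: AlleleFrequencyTable, ds: GenotypeDataset
) -> dict[str, PopGenSummary]:
    """Observed and expected heterozygosity per population.

    H_obs is the fraction of non-missing genotypes that are heterozygous;
    H_exp is gene diversity ``1 - sum p^2``; both averaged over loci.  The
    unbiased H_exp applies the ``2n/(2n-1)`` small-sample correction per
    locus before averaging.
    """
    out: dict[str, PopGenSummary] = {}
    for pop in freqs.populations:
        rows = ds.population_of(pop)
        if rows.size == 0:
            continue
        ho, he, heu, k_per_locus = [], [], [], []
        for j, locus in enumerate(ds.locus_names):
            geno = ds.calls[rows, j, :]
            ok = geno[:, 0] != MISSING
            if not ok.any():
                continue
            g = geno[ok]
            ho.append(float(np.mean(g[:, 0] != g[:, 1])))
            p = np.array(list(freqs.frequencies(pop, locus).values()))
            gd = 1.0 - float(np.sum(p**2))
            he.append(gd)
            n2 = 2 * int(ok.sum())
            heu.append(gd * n2 / (n2 - 1) if n2 > 1 else float("nan"))
            k_per_locus.append(len(p))
        out[pop] = PopGenSummary(
            population=pop,
            n_individuals=int(rows.size),
            h_obs=float(np.mean(ho)),
            h_exp=float(np.mean(he)),
            h_exp_unbiased=float(np.mean(heu)),
            mean_alleles=float(np.mean(k_per_locus)),
            total_alleles=int(np.sum(k_per_locus)),
        )
    return out


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def _prob_present(N: int, Ni: int, g: int) -> float:
    """P(allele with Ni of N copies appears in a subsample of g copies)."""
    return float(1.0 - hypergeom.pmf(0, N, Ni, g))


def default_rarefaction_g(freqs: AlleleFrequencyTable) -> int:
    """Smallest per-locus gene-copy count over scored population x locus cells."""
    sizes = [
        freqs.n_copies(pop, locus)
        for pop in freqs.populations
        for locus in freqs.loci
        if freqs.n_copies(pop, locus) > 0
    ]
    if not sizes:
        raise ValueError("no scored population x locus cells")
    return min(sizes)


def rarefied_allelic_richness(
    freqs: AlleleFrequencyTable, g: int | None = None
) -> pd.DataFrame:
    """Expected allele count in a subsample of ``g`` gene copies.

    ``E[k] = sum_i (1 - C(N - N_i, g) / C(N, g))`` per population x locus;
    at ``g = 1`` this is exactly 1 for any scored locus and at ``g = N`` it
    is the observed allele count.
    """
    if g is None:
        g = default_rarefaction_g(freqs)
    if g < 1:
        raise ValueError("g must be >= 1")
    rows = {}
    for pop in freqs.populations:
        rows[pop] = {}
        for locus in freqs.loci:
            c = freqs.counts[pop].get(locus)
            if not c:
                rows[pop][locus] = np.nan
                continue
            N = sum(c.values())
            if g > N:
                rows[pop][locus] = np.nan
                continue
            rows[pop][locus] = sum(_prob_present(N, Ni, g) for Ni in c.values())
    return pd.DataFrame(rows).T.reindex(index=freqs.populations, columns=freqs.loci)


def rarefied_private_alleles(
    freqs: AlleleFrequencyTable, g: int | None = None
) -> pd.Series:
    """Expected number of private alleles in subsamples of ``g`` gene copies.

    For allele i and population j, ``Q_ij`` is the probability the allele
    appears in a size-g subsample from j; the expected private-allele count
    of j is ``sum_i Q_ij * prod_{k != j} (1 - Q_ik)``, averaged over loci.
    """
    if len(freqs.populations) < 2:
        raise ValueError("private-allele rarefaction needs >= 2 populations")
    if g is None:
        g = default_rarefaction_g(freqs)
    if g < 1:
        raise ValueError("g must be >= 1")
    for pop in freqs.populations:
        for locus in freqs.loci:
            n = freqs.n_copies(pop, locus)
            if 0 < n < g:
                raise ValueError(
                    f"g={g} exceeds {n} gene copies of population {pop!r} "
                    f"at locus {locus!r}"
                )
    per_pop = {pop: [] for pop in freqs.populations}
    for locus in freqs.loci:
        alleles = freqs.alleles(locus)
        if not alleles:
            continue
        scored = [p for p in freqs.populations if freqs.n_copies(p, locus) > 0]
        Q = np.zeros((len(alleles), len(scored)))
        for jj, pop in enumerate(scored):
            c = freqs.counts[pop][locus]
            N = sum(c.values())
            for ii, a in enumerate(alleles):
                Ni = c.get(a, 0)
                Q[ii, jj] = _prob_present(N, Ni, g) if Ni else 0.0
        for jj, pop in enumerate(scored):
            others = np.prod(1.0 - np.delete(Q, jj, axis=1), axis=1)
            per_pop[pop].append(float(np.sum(Q[:, jj] * others)))
    return pd.Series(
        {p: (float(np.mean(v)) if v else np.nan) for p, v in per_pop.items()}
    ).reindex(freqs.populations)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(
    geno_by_pop: list[np.ndarray],
) -> tuple[float, float, float]:
    """Summed a, b, c variance components over alleles at one locus.

    ``geno_by_pop`` holds, per population, an (n_i, 2) array of non-missing
    allele sizes.  Components follow Weir & Cockerham (1984) with r = number
    of populations.
    """
    r = len(geno_by_pop)
    n = np.array([g.shape[0] for g in geno_by_pop], dtype=float)
    if (n < 1).any() or n.sum() < 2:
        return (np.nan, np.nan, np.nan)
    nbar = n.mean()
    if nbar <= 1:
        return (np.nan, np.nan, np.nan)
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_by_pop]))
    A = B = C = 0.0
    for allele in alleles:
        p = np.array([np.mean(g == allele) for g in geno_by_pop])
        h = np.array(
            [np.mean((g == allele).sum(axis=1) == 1) for g in geno_by_pop]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return (A, B, C)


def weir_cockerham_theta(
    ds: GenotypeDataset, populations: Iterable[str] | None = None
) -> float:
    """Multilocus Weir & Cockerham theta over the given populations.

    ``theta = sum_l sum_alleles a / sum_l sum_alleles (a + b + c)`` with
    locus-specific non-missing sample sizes; negative estimates are returned
    as computed.
    """
    pops = list(populations) if populations is not None else ds.population_labels
    rows = {p: ds.population_of(p) for p in pops}
    num = den = 0.0
    usable = False
    for j in range(ds.n_loci):
        geno_by_pop = []
        for p in pops:
            g = ds.calls[rows[p], j, :]
            g = g[g[:, 0] != MISSING]
            geno_by_pop.append(g)
        if any(g.shape[0] < 2 for g in geno_by_pop):
            continue
        a, b, c = _wc_components_locus(geno_by_pop)
        if math.isnan(a):
            continue
        usable = True
        num += a
        den += a + b + c
    if not usable:
        warnings.warn(f"no locus with >= 2 usable individuals per population in {pops}")
        return float("nan")
    return num / den if den != 0 else 0.0


def pairwise_fst_wc(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise multilocus theta between all populations (two-pop subsets)."""
    pops = ds.population_labels
    n = len(pops)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        theta = weir_cockerham_theta(ds, [pops[i], pops[j]])
        m[i, j] = m[j, i] = theta
    return DistanceMatrix(pops, m, allow_negative=True, name="fst_wc")


# ---------------------------------------------------------------------------
# Nei standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs: AlleleFrequencyTable) -> DistanceMatrix:
    """Nei (1972) standard distance ``D = -ln I`` between all populations.

    ``I = J_xy / sqrt(J_x J_y)`` where the J terms are arithmetic means
    across shared loci of ``sum p_x p_y``, ``sum p_x^2`` and ``sum p_y^2``.
    Disjoint allele sets give I = 0 and D = +inf (reported, not capped).
    """
    pops = freqs.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        jx, jy, jxy = [], [], []
        for locus in freqs.loci:
            fx = freqs.frequencies(pops[i], locus)
            fy = freqs.frequencies(pops[j], locus)
            if not fx or not fy:
                continue
            jx.append(sum(p * p for p in fx.values()))
            jy.append(sum(p * p for p in fy.values()))
            jxy.append(sum(fx[a] * fy.get(a, 0.0) for a in fx))
        if not jxy:
            raise ValueError(
                f"populations {pops[i]!r} and {pops[j]!r} share no scored loci"
            )
        I = np.mean(jxy) / math.sqrt(np.mean(jx) * np.mean(jy))
        m[i, j] = m[j, i] = float("inf") if I <= 0 else -math.log(min(I, 1.0))
    return DistanceMatrix(pops, m, name="nei_distance")


# ---------------------------------------------------------------------------
# Garza-Williamson M
# ---------------------------------------------------------------------------

def garza_williamson_m(ds: GenotypeDataset) -> pd.DataFrame:
    """Garza-Williamson ``M = k / (r + 1)`` per population x locus.

    ``k`` is the number of distinct alleles and ``r`` the allele-size range
    in repeat units ``(max - min) / motif_length``; a monomorphic locus has
    M = 1.  A range not divisible by the motif is rounded to the nearest
    whole repeat with a warning.  The ``mean`` column averages loci.
    """
    freqs = allele_frequencies(ds)
    motif = {l.name: l.motif_length for l in ds.loci}
    rows = {}
    for pop in freqs.populations:
        rows[pop] = {}
        for locus in freqs.loci:
            c = freqs.counts[pop].get(locus)
            if not c:
                rows[pop][locus] = np.nan
                continue
            sizes = sorted(c)
            k = len(sizes)
            span = sizes[-1] - sizes[0]
            r_exact = span / motif[locus]
            r = round(r_exact)
            if abs(r_exact - r) > 1e-9:
                warnings.warn(
                    f"{pop}/{locus}: allele-size range {span} bp not divisible "
                    f"by motif {motif[locus]}; rounded to {r} repeat units"
                )
            rows[pop][locus] = k / (r + 1)
    df = pd.DataFrame(rows).T.reindex(index=freqs.populations, columns=freqs.loci)
    df["mean"] = df[freqs.loci].mean(axis=1)
    return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

@dataclass
class HWETestResult:
    population: str
    locus: str
    observed_het: int
    expected_het: float
    p_value: float
    n_permutations: int
    seed: int | None
    monomorphic: bool = False


def hwe_permutation_test(
    ds: GenotypeDataset,
    pop: str,
    locus: str,
    n_perm: int = 9999,
    seed: int | None = None,
) -> HWETestResult:
    """Monte-Carlo HWE test by random re-pairing of gene copies.

    The statistic is the heterozygote count; the two-sided p-value is the
    +1-corrected proportion of permutations whose ``|het - E[het]|`` is at
    least the observed deviation, where E[het] is the permutation-null mean.
    """
    rows = ds.population_of(pop)
    j = ds.locus_names.index(locus)
    geno = ds.calls[rows, j, :]
    geno = geno[geno[:, 0] != MISSING]
    n = geno.shape[0]
    if n < 5:
        raise ValueError(f"{pop}/{locus}: need >= 5 non-missing genotypes, got {n}")
    copies = geno.ravel()
    if np.unique(copies).size == 1:
        return HWETestResult(pop, locus, 0, 0.0, 1.0, n_perm, seed, monomorphic=True)
    obs_het = int(np.sum(geno[:, 0] != geno[:, 1]))
    rng = np.random.default_rng(seed)
    # vectorised re-pairing: each row of `order` is a permutation of the pool
    order = np.argsort(rng.random((n_perm, copies.size)), axis=1)
    pairs = copies[order].reshape(n_perm, n, 2)
    hets = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
    e_het = float(hets.mean())
    dev = abs(obs_het - e_het)
    p = (1 + int(np.sum(np.abs(hets - e_het) >= dev - 1e-12))) / (1 + n_perm)
    return HWETestResult(pop, locus, obs_het, e_het, p, n_perm, seed)


def _enumerate_het_distribution(allele_counts: list[int]) -> dict[int, float]:
    """Exact null distribution of the heterozygote count given allele counts.

    Levene's conditional distribution: the probability of a genotype-count
    table f given allele counts a is ``n! * prod a_i! * 2^H / ((2n)! /
    (2n)!/...)``; implemented by recursive enumeration of tables, feasible
    for small n.
    """
    a = [c for c in allele_counts if c > 0]
    n2 = sum(a)
    assert n2 % 2 == 0
    n = n2 // 2
    k = len(a)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    dist: dict[int, float] = {}
    log_norm = (
        math.lgamma(n + 1)
        + sum(math.lgamma(ai + 1) for ai in a)
        - math.lgamma(n2 + 1)
    )

    def rec(idx: int, remaining: list[int], het: int, log_w: float):
        if idx == len(pairs):
            if all(r == 0 for r in remaining):
                dist[het] = dist.get(het, 0.0) + math.exp(log_norm + log_w)
            return
        i, j = pairs[idx]
        max_f = min(remaining[i], remaining[j]) if i != j else remaining[i] // 2
        for f in range(max_f + 1):
            rem = remaining.copy()
            if i == j:
                rem[i] -= 2 * f
                lw = log_w - math.lgamma(f + 1)
                rec(idx + 1, rem, het, lw)
            else:
                rem[i] -= f
                rem[j] -= f
                lw = log_w + f * math.log(2) - math.lgamma(f + 1)
                rec(idx + 1, rem, het + f, lw)

    rec(0, a, 0, 0.0)
    total = sum(dist.values())
    return {h: p / total for h, p in dist.items()}


def hwe_exact_enumeration(ds: GenotypeDataset, pop: str, locus: str) -> HWETestResult:
    """Full-enumeration exact HWE test for tiny samples (cross-check).

    Two-sided on ``|het - E[het]|`` under Levene's conditional distribution.
    Intended for <= 8 genotypes; enumeration grows quickly beyond that.
    """
    rows = ds.population_of(pop)
    j = ds.locus_names.index(locus)
    geno = ds.calls[rows, j, :]
    geno = geno[geno[:, 0] != MISSING]
    copies = geno.ravel()
    alleles, counts = np.unique(copies, return_counts=True)
    if alleles.size == 1:
        return HWETestResult(pop, locus, 0, 0.0, 1.0, 0, None, monomorphic=True)
    obs_het = int(np.sum(geno[:, 0] != geno[:, 1]))
    dist = _enumerate_het_distribution([int(c) for c in counts])
    e_het = sum(h * p for h, p in dist.items())
    dev = abs(obs_het - e_het)
    p = sum(p for h, p in dist.items() if abs(h - e_het) >= dev - 1e-12)
    return HWETestResult(pop, locus, obs_het, e_het, min(p, 1.0), 0, None)


# ---------------------------------------------------------------------------
# combined summary
# ---------------------------------------------------------------------------

def population_summary(
    ds: GenotypeDataset,
    g: int | None = None,
    m_pooling: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population table: n, H_obs, H_exp (raw and unbiased), allele
    counts, rarefied richness and private alleles, Garza-Williamson M.

    ``m_pooling`` optionally relabels populations (e.g. pooling islands) for
    the M statistic only, matching common bottleneck-test practice.
    """
    from .genotype_data import pool_populations

    freqs = allele_frequencies(ds)
    het = heterozygosity(freqs, ds)
    rich = rarefied_allelic_richness(freqs, g)
    priv = rarefied_private_alleles(freqs, g)
    m_ds = pool_populations(ds, m_pooling) if m_pooling else ds
    gw = garza_williamson_m(m_ds)["mean"]
    rows = []
    for pop in freqs.populations:
        s = het[pop]
        m_label = (m_pooling or {}).get(pop, pop)
        rows.append(
            {
                "population": pop,
                "n": s.n_individuals,
                "total_alleles": s.total_alleles,
                "mean_alleles": s.mean_alleles,
                "h_exp": s.h_exp,
                "h_exp_unbiased": s.h_exp_unbiased,
                "h_obs": s.h_obs,
                "rarefied_richness": float(rich.loc[pop].mean()),
                "rarefied_private": float(priv[pop]),
                "gw_m": float(gw.get(m_label, np.nan)),
            }
        )
    return pd.DataFrame(rows).set_index("population")
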