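# Methods

`ormiapop` re-implements, as one tested pipeline, the molecular-biogeography
analysis of an acoustically orienting parasitoid fly (*Ormia ochracea*) and
its cricket hosts: nuclear microsatellite population genetics, mitochondrial
COI haplotype networks, a host-song distance scheme, and permutation tests
relating genetic, geographic and acoustic distance matrices.  This note
records the statistical models, the defaults and why they were chosen, and
the places where the design was genuinely open.

## Genotype model and quality control

A genotype dataset is a table of diploid allele calls — fragment sizes in
base pairs — for individuals × microsatellite loci, with one population
label per individual and an explicit missing marker.  Allele pairs are
unordered and stored sorted; a half-called genotype is treated as missing.
Loci carry a repeat-motif length (3, 4 or 6 bp here), used only by the
bottleneck statistic; allele sizes at a locus that are not mutually
congruent modulo the motif raise a validation warning, not an error, since
real fragment calls contain off-ladder alleles.

Filtering is two-stage and order matters: loci whose missing fraction
**strictly exceeds** 0.25 are removed first, then individuals still missing
data at more than 2 of the remaining loci.  Loci go first because a failed
marker should not count against the individuals typed at it; the reverse
order is available through the same two functions and its different outcome
is exercised in the tests.  Both filters are idempotent.

## Microsatellite statistics

All per-locus statistics use locus-specific non-missing sample sizes.

* **Heterozygosity.** H_obs is the fraction of non-missing genotypes that
  are heterozygous; H_exp is gene diversity `1 − Σ p²`; both averaged over
  loci.  The unbiased variant multiplies per-locus gene diversity by
  `2n/(2n−1)`.  Both raw and unbiased forms are reported because published
  tables rarely say which they used.
* **Rarefaction.** Richness standardised to `g` gene copies uses the
  hypergeometric expectation `E[k] = Σ_i (1 − C(N−N_i, g)/C(N, g))`; at
  `g = 1` this is exactly 1, at `g = N` the observed count.  Private-allele
  rarefaction multiplies each allele's presence probability in the focal
  population by its absence probability in every other population.  The
  rarefaction unit is gene copies (2 × individuals, minus missing), and the
  default `g` is the smallest scored per-locus copy count across
  populations — the most conservative common standard.
* **Weir–Cockerham θ.** Pairwise Fst is the 1984 variance-component
  estimator: components a (among populations), b (among individuals within
  populations) and c (within individuals) are computed per allele per
  locus on the two-population subset, and the multilocus estimate is
  `Σa / Σ(a+b+c)`.  Pairs are analysed as two-population subsets rather
  than by restricting a global analysis, matching standard pairwise-Fst
  practice.  Negative estimates are reported verbatim (the container flags
  them); truncation at zero would bias averages.
* **Nei's standard distance.** `D = −ln I` with
  `I = J_xy / √(J_x J_y)`, the J terms arithmetic means across shared loci
  of `Σ p_x p_y`, `Σ p_x²`, `Σ p_y²`.  Disjoint allele sets give `I = 0`
  and `D = +∞`, reported rather than capped; the neighbor-joining stage
  refuses infinite entries and says so.
* **Garza–Williamson M.** Per locus `M = k/(r+1)` with `k` the allele
  count and `r` the allele-size range in **repeat units**
  (`(max−min)/motif`).  Repeat units are the canonical definition; a range
  not divisible by the motif is rounded to the nearest whole repeat with a
  warning.  A monomorphic locus has M = 1.  Values well below 1 indicate a
  population that lost alleles faster than size range — the bottleneck
  signature.  Note the statistic is non-monotone at extreme bottlenecks:
  two surviving adjacent-ladder alleles give M = 1 again.
* **Hardy–Weinberg tests.** The test statistic is the heterozygote count;
  the null is built by re-pairing the population's gene copies into
  diploids at random (Monte-Carlo gamete shuffling), and the two-sided
  p-value is the +1-corrected proportion of permutations with
  `|het − E[het]|` at least the observed deviation.  "Exact" HWE software
  varies in algorithm; Monte-Carlo re-pairing was chosen because it scales
  to any allele number, and a full-enumeration exact test under Levene's
  conditional distribution is provided for small samples as an independent
  cross-check.  Island populations can be pooled for HWE and M through a
  population-relabelling option without affecting heterozygosity or Fst.

## Haplotype networks

Aligned COI sequences are collapsed by **exact identity**, with IUPAC
ambiguity codes compared literally.  Wildcard matching of N against
everything is non-transitive (A–N and N–G match but A–G do not), which
would make the haplotype count depend on input order; literal comparison is
reproducible.  This is the main threat to matching haplotype counts
published from other software, so a drop-ambiguous-columns mode is provided.
The network is a minimum spanning tree on pairwise Hamming distances built
by deterministic Kruskal (edges sorted by weight, then lexicographic node
pair).  Rather than emulating any randomised tie-breaking, non-tree edges
no heavier than the heaviest edge on the tree path between their endpoints
(plus an epsilon tolerance) are reported as alternative connections.
Haplotype diversity is `h = n/(n−1)(1 − Σf²)`, undefined (flagged NaN) for
populations with fewer than two sequences.

## Host-song distances

Each host species' calling song is one feature vector: dominant frequency
(kHz), pulse rate (pulses/s), ln pulses per chirp-or-trill, pulse duty
cycle, a song-type code, chirps per trill (stutter-trillers), and the
introductory-part pulse count and rate (complex stutter-trillers).  Song
type is one **ordinal** column (chirp = 0, trill = 1, stutter-trill = 2,
complex stutter-trill = 3) because the scheme treats "song type" as a
single variable among the z-scored set; a one-hot mode exists for
sensitivity analysis.  Conditional features are zero-filled where
inapplicable — the only reading under which a plain Euclidean distance is
defined for every species pair.  Columns are z-scored with sample SD
(n−1); constant columns are flagged and dropped.

The packaged host-song table resolves printed ranges to midpoints.  Its
duty-cycle column is a **synthetic proxy** (pulse rate × 15 ms nominal
pulse length, capped at 0.95) because per-species duty cycles are only in
the external data deposit; the file header says so.  Species-level
distances therefore reproduce the deposited matrix qualitatively (closest
and farthest pairs, the island host as outlier), not cell-for-cell.

Population-level song distance aggregates over host assemblages three
ways: mean over common hosts, minimum over common hosts, minimum over all
known hosts.  Shared hosts contribute zero-distance pairs, so the minimum
methods give 0 for populations sharing a host.  Structurally,
`min_any ≤ min_common ≤ avg_common` entrywise.

## Matrix tests and trees

Mantel tests correlate upper-triangle vectors (row-major, i < j) of two
matrices aligned **by label**, permuting rows and columns of the second
simultaneously; p-values are one-sided for positive association (the
directional hypothesis throughout) with the +1 correction, so
`p ≥ 1/(n_perm+1)`.  An exhaustive mode enumerates all n! permutations for
small n.

The partial Mantel statistic correlates the residuals of simple linear
regressions of each triangle on the conditioning triangle.  Published
permutation schemes differ and are not equivalent; the default here
permutes the response matrix's labels and recomputes residuals each time
(raw-data permutation), with residual permutation behind a flag.  Neither
is asserted to be "the" scheme behind any published table.

Neighbor joining follows the Saitou–Nei Q-criterion with a deterministic
lowest-label-pair tie-break.  Negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch, conserving path
lengths.  On additive matrices the algorithm recovers topology and branch
lengths exactly (tested against brute-force path matrices and cross-checked
against scikit-bio's implementation).

Geographic distances are great-circle (haversine, mean Earth radius
6,371 km) from coordinates.  Real analyses may supply their own matrix —
for the original study system the published distances were terrestrial
routes, which are deliberately not reproduced here, so Mantel runs on the
packaged coordinates are illustrative rather than table reproductions.

## The synthetic serial-founder generator

The generator emulates the structure the analysis assumes, with recorded
ground truth:

* **Microsatellites.** Ancestral allele frequencies per locus are one
  symmetric-Dirichlet draw (concentration 1.0) over 8 contiguous slots of a
  12-slot size ladder (motif 4 bp, start 160 bp).  Each chain step draws
  `2 N_f` founder gene copies from its source's current frequencies, then
  drifts `g` Wright–Fisher generations at census size `2N` with stepwise
  mutation (rate 5 × 10⁻⁴ per copy per generation, ±1 repeat, reflecting
  at the ladder bounds), then samples `n` diploids under Hardy–Weinberg.
  Populations are frozen once they found their successor, so drift-only
  runs conserve allele identity along the chain exactly — the pattern of
  terminal variation being a subset of source variation.
* **COI.** A pool of haplotypes is generated on a star genealogy with
  Jukes–Cantor mutations (Poisson per branch); pool frequencies then drift
  along the chain as a single haploid locus, so haplotype diversity erodes
  with each founding.  A standard n-coalescent mode exists for calibration
  tests (Watterson's E[S]).
* **Songs and assemblages.** Species songs are drawn from per-feature
  Gaussian laws (categorical for song type, conditional fields consistent
  with the drawn type).  Host assemblages are a window of 3 species sliding
  2 species per chain step, so neighbouring populations share hosts and
  song distance covaries with geography.
* **Geography.** Populations sit on an equatorial transect at 500 km
  spacing, with a configurable extra gap (default 3,500 km before the first
  island population) standing in for the ocean crossing.

The default nine-population scenario names its chain after the study's
populations (Florida → Texas → Oaxaca → Sonora → Arizona → California →
Oahu → Kauai → Hilo) with founder sizes (500, 200, 150, 120, 100, 30, 6, 8,
4 diploids) chosen so the replicate-mean heterozygosity and M gradients
mirror the observed direction — mild erosion westward, severe island
bottlenecks — not the observed magnitudes.  Sample sizes match the study's
per-population counts.  A separate strong-isolation-by-distance scenario
(smaller founder groups, longer drift at every step) is the regime in which
Mantel power is assessed.

What the generator does **not** emulate: migration or admixture between
established populations, selection, null alleles and genotyping error
(beyond uniform missingness injection), within-population geographic
substructure, recombination-free mtDNA realism beyond a single locus, and
perceptual weighting of song features.  Passing recovery tests therefore
show the pipeline detects serial-founder signal and isolation by distance
when present in this idealised form — not that real data are this clean.

Determinism: one integer seed drives every draw through
`numpy.random.default_rng`; a bundle regenerates bit-identically, and the
pipeline manifest records seeds and input hashes.

## Study sizes used in tests

Desk-scale checks use 100 replicates for simulation-recovery claims
(replicate-mean gradients, ≥95% subset rate, ≥90% Mantel power), 1,000
replicates for permutation-calibration rates (Mantel on 9-label matrices,
HWE on 200 individuals × 10 Dirichlet(2) alleles, 199 permutations each —
sizes chosen so the discrete heterozygote-count statistic is dense enough
for the nominal level to be meaningful), 100 random additive trees (n ≤ 8)
for NJ recovery, and 50 random instances (≤ 6 nodes) for exhaustive
spanning-tree comparison.

## Known limitations

* Exact-identity collapsing can split haplotypes that other software's
  ambiguity handling would merge; use the drop-ambiguous-columns mode to
  compare.
* The packaged song table's duty cycle is a proxy (above); cell-level
  reproduction of the deposited song matrix requires the deposit itself.
* M's interpretation assumes a size ladder; loci with non-ladder alleles
  get a rounded range and a warning.
* Partial-Mantel p-values depend on the permutation scheme; both are
  implemented, and results tables should state which was used.
* The Fst estimator is the two-population θ; it is not an AMOVA and does
  not model hierarchical structure.
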