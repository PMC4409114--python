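# Methods

## Coordinates and domain invariants

All in-memory coordinates are 1-based inclusive; length = end − start + 1.
BED input/output (0-based half-open) is converted only at the file
boundary. Chromosome labels are normalized by stripping a leading `chr`;
`X`/`Y` are the sex chromosomes.

A call is a (sample, population, interval, type, CN state) record.
Deletions carry CN 0 or 1 and duplications CN 3 or 4 on autosomes; CN 2
is admitted only on X/Y, where hemizygosity makes two copies a non-
reference state. Calls longer than 5.5 Mb are rejected at read time — an
observational cap (array surveys do not report events beyond that size,
and larger segments are usually artifacts), not a QC rule, so it is
overridable (`max_length=None`).

The size-inclusion filter is **strict**: a call is retained only if its
length exceeds 100,000 bp, so a 100 kb call is removed and a 100,001 bp
call kept. Smaller calls have poor signal-to-noise on arrays and are
excluded wholesale rather than risk asymmetric false-positive pruning.

## Matching and locus construction

Two calls on the same chromosome match when their overlap covers ≥ 50%
of *each* call (reciprocal overlap, computed on inclusive coordinates:
`o = min(end) − max(start) + 1`), or in exact-breakpoint mode when both
endpoints agree within a tolerance. Loci ("breakpoint regions") are the
connected components of the match graph — single linkage — so chained
overlaps merge into one region; this matches how shared-breakpoint counts
are tallied between populations, which tolerate chained overlaps. A
strict all-pairs mode is available for users who want every member pair
to match. Duplications and deletions never merge by default
(`type_aware=True`): losses and gains are analysed separately.

Single-linkage clustering is accelerated with an interval tree and is
verified in the tests against an O(n²) brute-force
pairwise-links-plus-connected-components oracle.

Jaccard concordance of two call sets uses greedy 1–1 matching by
descending overlap (ties: leftmost start, then smallest length — fully
deterministic), losses and gains matched separately and pooled:
J = matched / (|A| + |B| − matched). Two empty sets define J = 1.

Same-sample deduplication (default on in the pipeline) collapses a
sample's own calls that match at 50% reciprocal overlap within one
(type, chromosome) group, keeping the longest; merged multi-algorithm
call tables otherwise double-count carriers.

A call is *novel* relative to a reference catalogue when it matches no
reference interval under the active rule; an empty reference makes
everything novel, with a warning rather than an error.

## Sharing, conservation, frequencies

The sharing matrix counts **loci**, not call pairs: entry (i, j) is the
number of loci whose carriers span both populations. Pairs can be masked
as unavailable (NA) to mirror surveys with missing comparisons.

A locus present in at least 6 of the study populations (configurable) is
*conserved* — old enough to predate the separation of the groups. The
conserved ladder buckets loci by exact sharing level.

Carrier frequency is per breakpoint region: an individual carries a
locus if it contributes ≥ 1 member call; CN state does not affect
carrier status. Frequency classes are strict: recurring iff f > 0.70,
rare iff f < 0.05, the boundaries themselves falling in
moderately-recurring.

## Distances and trees

*Allele sharing*: the distance between two populations is the mean over
all cross-population individual pairs of the fraction of mismatching
loci in their carrier-genotype vectors.

*Nei (1972) standard distance* on carrier frequencies: each locus is
biallelic (carrier/non-carrier) with frequencies (f, 1−f);
`Jxy = mean_l Σ_a x_a y_a`, `Jx`, `Jy` analogous, and
`D = −ln(Jxy / √(Jx·Jy))`. By Cauchy–Schwarz the identity I ≤ 1, so
D ≥ 0, with D = 0 exactly for identical profiles. I ≤ 0 (possible only
with opposite fixation everywhere) raises a degenerate-input error. A
multi-allele mode (`nei_distance_cn`) accepts per-CN-state frequency
rows instead; the biallelic encoding is the default because sharing is
defined per breakpoint, not per state.

*Sharing counts → distances*: nothing canonical converts similarity
counts to distances, so both interpretations are provided —
`max_minus` (d = max defined count − count; preserves count differences
linearly; the default) and `one_minus_norm` (d = 1 − count/max). NA
pairs are imputed with the mean of the defined distances in their row
and column and logged.

*Neighbor-joining* (Saitou–Nei): joins the pair minimizing
Q(i,j) = (n−2)d(i,j) − r_i − r_j with the standard branch-length
formulas; exact on additive matrices (property-tested on random trees of
4–8 taxa and cross-checked against an independent implementation).
Negative branch lengths are clamped to zero, transferring the deficit to
the sibling branch so the pair's span is preserved, and logged.

*UPGMA*: size-weighted average linkage; a merged node sits at height
d/2, so output is ultrametric by construction (checked to 1e−9) and
ultrametric inputs are recovered exactly. Merge heights are
cross-checked against SciPy average linkage.

Ties everywhere break on the lexicographically smallest pair of cluster
labels (a cluster is labelled by its smallest leaf), so repeated runs
give byte-identical Newick.

*Consensus*: strict (all trees) or majority (> 50%) bipartitions,
computed on unrooted topologies; unresolved regions collapse to
polytomies and branch lengths are omitted.

Trees are dendropy objects throughout, serialized as standard Newick.

## Synthetic cohort generator

The generator emulates the *called-CNV output* of a 12-population SNP-
array survey — not the arrays, and not demography. Packaged defaults:

| parameter | default | rationale |
|---|---|---|
| per-population (n, dup mean, del mean) | 12 profiles, e.g. Tibet (31, 27.00, 6.91), Australia (53, 35.21, 7.83), New World (41, 33.61, 13.90) | per-individual Poisson means of retained (>100 kb) calls in the emulated survey; pooled expectation ≈ 44,000 calls with a ≈ 74.7% gain share |
| size model | bins (100 k, 250 k, 500 k, 1 M, 2 M, 3 M, 4 M, 5.5 M] with masses 0.663, 0.223, 0.075, 0.03, 0.0065, 0.001, 0.0015; log-uniform within a bin | the canonical declining size spectrum; only bin masses are empirical, the within-bin law is the simplest scale-free choice |
| CN-state conditionals | DEL → {0: 0.15, 1: 0.85}, DUP → {3: 0.8, 4: 0.2} | loose calibration to published per-state spectra (heterozygous losses and single gains dominate); non-canonical, exposed in config |
| sex_chrom_fraction | 0.05 | small sex-chromosome burden (reported per-population means span ~1–7%); such calls are emitted with CN 2 |
| genome | hg18-like chromosome lengths | placement weight only |
| planted-locus carrier frequency | Beta(2, 5) floored at 0.05 | broad 3–70% spread matching reported conserved-locus frequencies; the floor keeps planted loci recoverable in small cohorts |

Background calls are placed uniformly on a length-weighted random
chromosome — the simplest null compatible with the downstream analyses.
`plant_sharing_ladder` places non-overlapping ancestral loci whose
population sets have exactly the requested cardinalities (uniformly
chosen), with bounded retries for placement.

Everything is driven by one `numpy` Generator, so a seed makes cohorts
bit-identical.

**What passing tests show, and what they don't.** Recovery of planted
ladders, burdens and spectra demonstrates that the analysis stages
compute what they claim on data with known structure. The generator has
no linkage, hotspots, platform batch effects, population structure
within panels, or CNV mutation process on a tree — so the tests validate
the *pipeline*, not any claim about real cohorts.

## Pipeline

`run_pipeline` executes filter → dedup → cluster → sharing → ladder →
frequencies → classification → spectra → novelty → distances → trees
from a YAML config, writing TSVs, Newick files, a JSON summary and a
log. A seed is mandatory for any synthetic input (no silent random
runs); unknown config keys are rejected. Stages can be restricted (e.g.
trees only, from a sharing-count matrix).

## Problem sizes and numerical choices

Tests exercise clustering up to n = 500 calls against the brute-force
oracle, trees up to 12 taxa, and full default cohorts (~44,000 calls) for
calibration; stochastic checks use fixed seeds and 3-sigma binomial /
3-SE Poisson bands against the generator's own parameters. Ultrametricity
tolerance is 1e−9; distance-matrix symmetry tolerance 1e−9.

## Known limitations

* Breakpoint precision is taken at face value from the call table; no
  probe-level refinement.
* "Carrier" ignores zygosity: a CN 0 and a CN 1 deletion carrier count
  equally.
* The sharing→distance conversions are interpretations, not canonical
  statistics; trees from `max_minus` and `one_minus_norm` can differ.
* Chi-square/P-value columns attached to published burden tables are not
  recomputed: the expected-value model behind them is not specified, so
  any reimplementation would be a guess.
* The generator's global gain share emerges from pooling the 12 profile
  means (≈ 74.7%); per-population shares vary widely by design.
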