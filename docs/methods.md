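# Methods

## Coordinate model

All internal coordinates are 0-based, half-open (BED convention); 1-based
positions in input tables (SNP positions, transcript TSS columns) are
converted at parse time. The overlap predicate everywhere is ≥ 1 bp of
half-open intersection, matching the default semantics of the interval
tooling this kind of analysis is normally built on (bedtools-style).

## Fragment maps and promoter windows

A chromosome is digested in silico at every GATC occurrence; the cut is
placed at the first base of the motif, the standard 3C fragment-map
convention. Fragments tile each chromosome exactly (asserted), and the
lower-resolution map concatenates k = 4 consecutive fragments per bin,
keeping a trailing partial group as a smaller bin so coverage is preserved.
A bin is bait-flagged if any member fragment is.

Promoter windows span −1500/+500 bp of the TSS, strand-aware: on the minus
strand the window is reflected so "upstream" still means 5′ of the gene.
Windows are clipped at chromosome edges (the clipped-window behaviour is a
deliberate choice; the alternative — strand-unaware windows — changes
nothing in the synthetic benchmarks but is scientifically wrong for minus
strand genes). A fragment is a bait iff it overlaps ≥ 1 bp of any window.

## Reference OCR atlas

Per cell type, replicate peaks are union-merged with bookended (distance-0)
intervals coalescing; a merged peak's support is the number of *replicates*
contributing ≥ 1 overlapping peak (a replicate never counts twice), and
peaks with support < 2 are removed. Cell-type sets are merged again into
reference OCRs; any OCR overlapping a blacklist interval is dropped; ids
are the deterministic `chrom:start-end`. An OCR is *open* in a cell type
iff any single replicate peak of that cell type overlaps it — deliberately
more permissive than the 2-replicate rule used for constructing the
reference set.

The count-based retention filter keeps an OCR iff at least
`ceil(0.5 × n_samples)` samples individually reach 1.5 CPM
(CPM = count × 10⁶ / library size). "Top 50% of samples" is ambiguous
between a per-sample threshold and a rank-based rule; the per-sample
reading is implemented (the read-count equivalent of 1.5 CPM at these
library sizes supports it) and both the threshold and the fraction are
configurable. The comparison is inclusive: exactly 1.5 CPM passes, because
the removal rule targets regions with *less than* 1.5 CPM support.
Differential accessibility testing itself (edgeR/limma) is out of scope;
the atlas exposes counts and this filter only.

## Interaction projection

Significance scores are thresholded inclusively at 5 (the upstream caller's
convention is quoted both as "score > 5" and as a "lower threshold of 5";
inclusive is implemented and configurable). Merging the two resolutions
collapses only coordinate-identical records (both ends equal after
canonical lower-coordinate-first ordering), keeping the maximum score; a
1-fragment call nested inside a 4-fragment bin is *not* treated as
redundant — projection unions their evidence anyway, so the distinction is
immaterial downstream but keeps the merged file faithful to its inputs.

Projection emits an OCR pair when any significant call at either resolution
links fragments overlapping both OCRs, with both OCRs open in the cell
type; trans and self pairs are excluded; pairs where neither OCR overlaps a
promoter window are removed; each end is classed `prOCR`/`nonprOCR` by its
own promoter-window overlap. Pair distance is the absolute difference of
OCR midpoints (symmetric, anchor-free). Bait-to-bait (promoter-promoter)
contacts are projected like any other. Outputs are sorted by coordinates so
repeated runs are byte-identical.

## Variant-to-gene mapping

r² thresholds are inclusive (≥ 0.8 strict, ≥ 0.4 relaxed): published
variant lists retain proxies at exactly the nominal cutoff, so ">" is read
as "≥". Sentinels present in the proxy table ride along as their own
proxies with r² = 1. An accessible variant is a proxy whose position falls
inside an OCR open in the chosen cell type (the atlas is non-overlapping,
so at most one).

Two routes produce (SNP, gene) pairs: *promoter residency* (the SNP
position inside a gene's promoter window, within an open OCR) and
*interaction* (each gene whose promoter window overlaps a partner OCR of
the SNP's OCR). Residency does not by itself contribute to the
interaction-route gene set — the two tallies are reported separately, as
the source analysis tabulates them.

The nearest gene is the gene minimizing TSS distance to the SNP position
over all its transcripts, ties broken by lexicographic gene id. The gene
universe defaults to captured-promoter genes (≥ 1 promoter window
overlapping a bait fragment) with an `all`-genes switch. Each proxy with a
non-empty interaction-route gene set gets exactly one category:
`nearest_only` (set = {nearest}), `nearest_plus_distant` (nearest plus
others), `skip` (nearest absent). The upstream presentation sometimes
splits these into four display categories; the three-way scheme is what the
percentages (8.5 / 29 / 62.5) describe, and is what is implemented.

## Empirical overlap test

The candidate pool is every (sentinel, gene) pair with ≥ 1 gene TSS within
± 5 Mb of the sentinel. Each of `reps` iterations draws as many pairs as
the observed map contains, uniformly *without replacement* (the observed
set consists of distinct pairs; a with-replacement switch exists), and
counts the overlap with the eQTL pair set, matched on (sentinel,
uppercased gene symbol). The Monte-Carlo p-value uses the add-one
correction p = (1 + #{null ≥ observed}) / (reps + 1), so it is never 0 and
never below 1/(reps+1); "expected" overlap is the null mean, and fold
enrichment is observed / null mean (undefined at null mean 0). Draws are
implemented as the m smallest of n iid uniform keys per repetition —
exactly uniform over m-subsets — vectorized in chunks; results are
byte-identical given the seed. The pool does not exclude observed pairs
(configurable): excluding them would anti-conservatively shrink the null.

One calibration note: with the add-one formula the p-value is discrete and
super-uniform (conservative) whenever the overlap statistic has few support
points; a Kolmogorov–Smirnov check against continuous U(0,1) is then
guaranteed to reject for reasons that have nothing to do with correctness.
The uniformity check in the test suite therefore uses a null configuration
whose overlap statistic has wide support (pool of 2000 pairs, half flagged,
draws of 1000), where the discrete p-value is a fine-grained approximation
of a continuous one; the small-pool behaviour is instead checked directly
against exact enumeration of all possible draws.

The Fisher feature-enrichment statistic reports the sample odds ratio
`a·d / (b·c)` (undefined on a zero denominator) and the one-sided
(greater) Fisher exact p — the hypergeometric upper tail given the table
margins — via `scipy.stats.fisher_exact`.

## Synthetic data generator

The generator emulates the study's inputs on a toy genome, with defaults at
study scale: 4 chromosomes carrying 1200 genes on a 25 kb grid (TSS
jittered ± 2 kb, strands uniform), GATC sites Poisson-spaced at 4/kb (the
empirical DpnII density, giving ~250 bp fragments), 2 cell types × 3
replicates, 60 sentinels, 250 proxies planted in distal open chromatin
with the 8.5/29/62.5% category mix (largest-remainder rounding, so the
planned counts are exact), 60 promoter-resident proxies, 150 inaccessible
proxies, sentinels riding along as their own r² = 1 proxies, significance
scores uniform on [5, 20] with sub-threshold decoys on [0.5, 5), contact
distances within 1 kb–1.5 Mb, r² drawn from a mixture across the 0.8
boundary so threshold sweeps change the retained set, and an eQTL list
holding 19 planted overlapping sentinel-gene pairs among 84 — chosen so the
default run reproduces the scale of the motivating analysis (observed 19
vs. ~1.8 expected, ~10-fold).

Each inter-gene interval hosts one distal OCR slot plus a free zone for
sentinels, inaccessible proxies and noise peaks, so planted elements cannot
collide. True OCRs open in the focal cell type are guaranteed support from
≥ 2 replicates (so planted paths survive the consensus filter;
reproducibility governs the third replicate), while noise peaks appear in
exactly one replicate and must be removed by it. Planted contacts are
emitted at 1-fragment, 4-fragment, or both resolutions; a 4-fragment
record is only emitted after verifying its bins touch no foreign promoter
OCR or proxy-bearing OCR (± 60 bp, covering replicate-peak jitter),
falling back to 1-fragment resolution otherwise — this is what makes
per-SNP category recovery *exact* rather than approximate. Counts are
Poisson (mean 30 for open, 0.5 closed, 1 noise at 2 M library size) so
true-open OCRs pass and noise rows fail the CPM rule.

What the generator does not emulate: read-level noise, irreproducible
interaction calls, LD structure beyond assigned r² values, overlapping
genes/promoters, trans contacts, and copy-number or mappability artifacts.
Passing tests therefore demonstrate the *logic* of the pipeline (filters,
projection, categorization, calibration) on clean inputs, not robustness
to the pathologies of real libraries.

## Problem sizes and determinism

The test suite runs a small study (2 chromosomes, 120 genes, 30 categorized
proxies) through every stage, a 2000-proxy cohort for category recovery, a
100-instance oracle-equivalence sweep for projection, and 500 × 500-rep
datasets for p-value calibration — sizes chosen so the whole suite finishes
in well under a minute while every check retains statistical power. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; generator streams are derived as `default_rng([seed, stage])`, and
equal seeds give byte-identical files, results and manifests (timestamps
excepted).

## Known limitations

- The atlas carries openness as a binary call; quantitative accessibility
  beyond the CPM filter (normalization, differential testing) is out of
  scope, as are peak calling, read alignment and the interaction caller's
  statistical model itself.
- Reference OCR coordinates come from merged *jittered* peaks, so they can
  differ from true planted intervals by up to the jitter; truth comparisons
  are therefore made at the SNP/gene level, not the OCR-id level.
- `connectivity_stats` counts distinct partner OCRs per gene; it does not
  deduplicate partners shared between a gene's multiple promoter OCRs
  across cell types.
- The empirical test treats the eQTL list as fixed; uncertainty in the
  eQTL calls themselves is not propagated.
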