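# Methods

`pansv-atlas` re-implements, as a reusable and tested library, the
analytical core of a pangenomic structural-variant (SV) study design for an
allotetraploid crop cohort: per-accession call-set filtering, read-depth
segmental presence/absence (PAV) calling, cross-accession merging into a
pangenome locus matrix, hotspot detection, a windowed Weir–Cockerham F_ST
selection scan, ecotype enrichment statistics, transposable-element (TE)
tagging, and saturation analysis. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
cohorts do and do not establish.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; conversion to/from the
1-based VCF and GFF3 conventions happens only at the I/O boundary. For
symbolic DEL/INV records, POS is treated as the first affected base and the
span is `[POS-1, END)`; when SVLEN is present it takes precedence (htslib
re-derives the end from SVLEN under the base-before convention, so relying
on its computed stop would shift spans by one). Allele frequency falls back
to `DV/(DR+DV)` when the caller wrote no AF tag, and is undefined when no
reads are recorded.

## Filter cascade

The cascade mirrors a dual-caller long-read workflow. Thresholds
(all inclusive, `>=`): QUAL 50, GQ 50, DV 12, SV length 30 bp, allele
frequency 0.9 with precise breakpoints, and a minimum read support of
`ceil(0.4 x mean coverage)` per accession. Consensus between the two
callers keeps a record iff the other caller holds an unconsumed record of
the same type on the same chromosome within 1000 bp of the start; pairing
is greedy nearest-first with deterministic left-to-right tie-breaking
(breakpoint-distance semantics, not reciprocal overlap, matching the
behaviour of distance-based SV mergers). Calls overlapping a >=10-kbp
deleted segment of the same accession are removed; duplication segments
never remove calls. Assembly-based inversion call sets are reduced to
PASS `<INV>` records.

## Read-depth segments and gene PAV

Coverage is binned at 1 kbp (a bin small enough to resolve the 10-kbp
minimum with ten bins while keeping the genome-wide SD stable). Bins with
depth > 150 are discarded as unalignable outliers *before* the mean mu and
sample SD sigma are computed, and a discarded bin splits any run. Maximal
runs of consecutive bins all below mu - sigma (deletions) or above
mu + sigma (duplications) spanning >= 10 kbp become segment calls; mu and
sigma are genome-wide per accession, not per chromosome, because a single
threshold is applied across the genome. Constant coverage (sigma = 0) is a
valid degenerate input and yields no segments. Runs are strictly
contiguous; a single non-deviating bin splits a run (a gap-tolerant variant
would merge across isolated noise bins but was not adopted, to keep the
rule faithful and simple). Genes overlapping a segment by >= 1 bp inherit
its state; when both classes overlap, the larger total overlap wins and
ties go to DELETED. Ecotype-correlated gene PAV uses the inclusive
>= 70% / <= 30% rule with the admixed semi-winter East Asian group excluded
from the comparison set.

## Merging into pangenome loci

Clustering is single-linkage per chromosome per SV type, which makes the
result independent of accession input order. Two records are mergeable
when their start distance is at most `min(1000, max(100, 0.5 x min(len)))`
— a nonlinear tolerance that scales with SV size and is capped at 1000 bp
(a fixed-1000 mode is available) — and their alleles are compatible:
insertions need >= 90% identity (`1 - editdist/max(len)`, edlib), deletions
and inversions need a reciprocal length ratio >= 0.9 (their reference
sequence is shared by construction, so the ratio bounds the identity), and
translocations merge by distance alone. Within a cluster at most one
record per accession is kept (nearest to the cluster's mean start, with
content-based tie-breaking), and the representative is the member with the
smallest (start, accession) key. Because representatives of distinct loci
are pairwise non-mergeable by construction, merging is idempotent.

## Hotspots and subgenome asymmetry

Chromosomes are tiled with non-overlapping 200-kbp windows (final window
keeps its true width so telomere-proximal SVs are not dropped); the window
value is the number of locus start coordinates it contains. Hotspots are
the top 30% of windows per subgenome, `floor(0.3 W)` windows extended
through ties at the boundary value — ties share the boundary count, so
truncating them would be arbitrary. Subgenome A vs C density is compared
with a pooled-variance one-tailed Student's t (alpha = 0.01) on per-window
percentages of the genome-wide total; all-equal groups are reported exactly
as t = 0, p = 0.5, and zero pooled variance with unequal means as p below
machine precision.

## Selection scan

For a biallelic presence/absence locus scored in two populations of
homozygous diploids, the two-population Weir–Cockerham variance components
a, b, c are computed with the observed heterozygosity term h̄ = 0 (carriers
are 1/1, non-carriers 0/0). Per non-overlapping 50-kbp window the weighted
estimate `sum(a) / sum(a+b+c)` is taken over loci starting in the window
(monomorphic loci skipped, windows with no usable locus omitted); a
mean-of-ratios column is emitted alongside for comparison. Negative
window values are retained — clamping would distort the mean and SD used
next. Window values are standardised as `z = (x - mu)/sigma` with mu and
sigma over all windows of the comparison (sample SD), and windows with
z >= 1.645 (inverse standard-normal CDF at 0.95; the comparison is
inclusive and configurable) merge, when adjacent, into candidate regions
annotated with overlapping genes.

Calibration: the empirical exceedance of mean + 1.645 SD equals 5% only to
the extent the cross-window F_ST distribution is normal. With ~100 loci
per window (the many-locus regime; dense pangenome call sets reach this
easily) the null flagged fraction sits at ~5-6%; at ~10 loci per window
the distribution is visibly right-skewed and the exceedance is nearer
6-7%. The calibration study in the tests therefore uses 2000 windows of
100 loci; the power study uses the sparser 10-loci windows where a planted
0.9-vs-0.1 contrast (n = 20 per group) is flagged essentially always.

## Enrichment and saturation

Over/under-representation uses the inclusive 70/30 carrier-fraction rules,
again excluding the East Asian group from the comparison set. Association
per locus x ecotype is a two-sided Fisher exact test — the probability-mass
rule, computed from the vectorised hypergeometric pmf with a declared
probability-tie tolerance of 1e-7 — with Haldane–Anscombe +0.5 on all cells
for the odds ratio whenever any cell is zero, and Benjamini–Hochberg
step-up adjustment applied once across all tests of a run. The saturation
curve samples k accessions without replacement (k = 1..N, 1000 iterations,
seeded) and counts distinct genes present in at least one sampled
accession; the mean is non-decreasing in k by union monotonicity and the
k = N point equals the exact union with zero SD.

## TE tagging

The matcher emulates ungapped BLASTN at `-perc_identity 99` with
`-max_target_seqs 1`: exact 11-mer seeds locate shared diagonals (both
strands), each seeded diagonal contributes its maximum-score ungapped
segment (match +1, mismatch -2; ties prefer the shorter then the leftmost
segment), and a segment is reported only with identity >= 0.99 over
>= 30 bp, the longest valid segment winning. The 30-bp floor replaces the
e-value cut-off, which would require a database-size model this analysis
does not define — the one deliberate deviation from the BLAST parameter
set. Score-maximal extension matters: a "longest window with >= 99%
identity" rule would report the ~30-80-bp exact runs that arise by chance
inside 5%-diverged sequence pairs, whereas extension through to one long
low-identity segment lets the identity filter reject them, as BLAST does.
Zones are evaluated independently per locus: the allele sequence (INS) or
reference span (INV), and the 100-bp flanks upstream of the start and
downstream of the end (truncated at chromosome ends). The pipeline tags
insertions and inversions, the two classes the procedure is defined for.

## Synthetic cohorts

The generator's default cohort is the package's standard study condition:
22 accessions in four ecotype groups (WOSR 6 / SOSR 6 / East Asian OSR 6 /
swede 4 — a 94-accession panel's 22/23/22/17 proportions scaled by ~1/4)
on two 10-Mbp chromosomes, one per subgenome, with ~7200 planted loci
(~4-5k calls per accession), baseline depth 40 +/- 8 per 1-kbp bin, and two
pseudo-callers. Design points:

- Planted loci sit on a grid spaced >= 2.2 kbp, so distinct loci can never
  chain together under the <= 1-kbp merge distance; breakpoint jitter
  (<= 50 bp per caller, independent) preserves >= 2.1-kbp gaps.
- Carrier patterns: shared loci (frequency ~U(0.7, 1)), ecotype-specific
  loci (0.8 in the target group, 0.05 elsewhere), private singletons, and
  optional differentiated loci (0.9 vs 0.1 between configured groups).
  Hotspot windows receive a 4x placement weight; subgenome A a 1.3x weight.
- Insertion alleles are random sequence; a configurable fraction (0.3)
  embeds a verbatim subsequence of a 12-family TE library. Per-carrier
  allele copies carry ~1% substitutions, capped at 2.5% of the length so
  pairwise divergence stays <= 5%, and never inside the embedded TE copy —
  a fresh TE insertion is near-identical to its source element, and the
  >= 99%-identity tag must remain attainable.
- Coverage segments (>= 12 kbp, bin-aligned) shift depth by 0.1x
  (deletions) or 2.5x (duplications). 2.5x rather than 3x keeps planted
  duplications ~6 SD below the 150-depth discard cut-off so in-segment
  noise cannot split a run. Isolated outlier bins at depth 500 exercise
  the discard rule. Spurious good-quality calls are planted inside deleted
  segments, in both callers, so only the overlap filter can remove them.
- Both pseudo-callers emit every true call (with independent jitter and a
  6% chance of a degraded copy: low QUAL, heterozygous, imprecise, or low
  DV) plus independent false positives, so consensus filtering is
  meaningfully exercised.
- All draws flow from one seed through named child streams (slots, loci,
  segments, per-accession coverage, per-accession call sets, in that
  order); outputs are byte-identical across reruns.

What passing tests show — and do not. The cohorts have planted truth with
clean statistical structure: no alignment artefacts, no homoeologous
mis-mapping, no GC or mappability bias in coverage, no indel errors in
alleles, and TE insertions that are exact library copies. Recovery rates
near 100% therefore validate the *logic* of the filters, the segment
caller, the merger, and the TE matcher under their stated assumptions; they
do not measure performance on real long-read call sets, where caller error
models and repeat structure dominate.

## Problem sizes and determinism

The default test and acceptance runs use the 22-accession / 2 x 10-Mbp
cohort end-to-end (~65 s per full pipeline run), a sparser 8-Mbp cohort
for recovery properties, and direct presence-matrix simulation (2000-2050
windows) for scan calibration and power. The pipeline fans one global
seed out to per-stage child seeds by stable hashing of stage names, writes
all outputs as text with fixed float formatting (6 significant digits at
the I/O boundary), and records the SHA-256 of every output in the run
manifest; two runs with the same config and seed are byte-identical.

## Known limitations

- The merger approximates DEL/INV sequence identity by the length ratio;
  true breakpoint micro-homology or allele re-alignment is out of scope.
- The depth caller has no GC correction and no HMM/CBS segmentation; it is
  the thresholded-run rule, by design.
- Translocations carry a single breakpoint and participate by distance
  only; no sequence logic is applied to them.
- The "coverage above 150" cut-off is treated as absolute depth (the
  cohorts average ~40x), not a normalised value.
- Heterozygous SVs are filtered out by design (allele frequency >= 0.9),
  trading recall for precision in a polyploid genome where homoeologous
  exchange inflates heterozygous artefacts.
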