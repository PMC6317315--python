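# Methods

This note documents the models, parameter choices and numerical
conventions behind `rubychip`, and what the synthetic tests do and do
not demonstrate.

## Coordinate and overlap conventions

All interval arithmetic uses 0-based half-open coordinates (BED
convention); GFF3 output converts to 1-based closed. "Overlap" always
means ≥ 1 shared base. Merging with a clustering distance `g` joins
intervals whose gap is *strictly* less than `g`; a gap of exactly `g`
keeps regions separate. Midpoints round down on half-base ties.
Clamping at chromosome edges truncates (it does not shift).

## Normalization

The bias-elimination step is a documented simplification of the
published BEADS approach (whose read-level GC/mappability weighting
lives in prior work): ChIP and summed-input tracks are scaled to equal
genome-wide mass (so any c > 0 library rescaling cancels exactly), the
input is smoothed with a flat kernel (default 500 bp), and the output
is `log2((chip + pc) / (input_smoothed + pc))` with pseudocount
`pc = 1` read-equivalent. Positions with mappability below 0.25 are
NaN; NaN is the only missing marker and is never conflated with 0.
bedGraph output encodes missing positions by omission. An optional
GC-stratified median correction (10 strata) is available behind a flag
but is off by default; the synthetic genome has no GC bias to correct.

Properties that hold by construction: antisymmetry in the two tracks at
`pc = 0`; invariance to library rescaling; masked output fraction equal
to the masked mappability fraction.

## Peak calling

A deliberately small local-lambda Poisson caller stands in for a full
model-based one. Windows of one fragment length (default 150 bp,
stepped by half) are scored as
`reads = coverage mass / fragment_len`, and tested against
`lambda = max(genome-wide rate, depth-scaled local control rate)`; in
no-control mode the local rates over 5-kb and 10-kb centered flanks
replace the control term. P-values are the Poisson upper tail at the
integerized count; q-values are Benjamini–Hochberg over all windows;
windows with q ≤ 0.05 merge when overlapping. The summit is the
leftmost position of maximum coverage in the merged region, and the
peak score follows the narrowPeak column-5 convention, −10·log₁₀ q
(q floored at 1e-300), so the blacklist rule "score < 100" is q > 1e-10.

The caller assumes Poisson noise; the simulator draws negative-binomial
background (overdispersed), so a handful of false-positive windows per
track is expected and realistic. These rarely survive replicate
intersection, which is the point of the consolidation design.

Blacklist construction runs the caller in no-control mode on each input
library separately, keeps peaks with score ≥ 100, and cluster-merges
survivors within 500 bp. A user-supplied external blacklist can be
unioned in.

## Consolidation

Summits are extended ±150 bp into 300-bp regions, replicate region sets
are intersected, and each non-empty intersection is re-centered at its
midpoint with the final width restored to 300 bp (clamped at edges).
The re-centering anchor for narrow intersections is a design choice
(the midpoint, for symmetry); an alternative would be
coverage-weighted. Peaks sharing ≥ 1 bp with a blacklist region, or
with mean mappability < 0.25, are dropped (a min-based mappability rule
is available by flag; the mean is the default because the per-base
threshold is the only stated rule and the mean is robust to single
masked bases).

## Annotation enrichment

Classification is exclusive with the fixed priority snRNA, snoRNA,
tRNA, miRNA, lincRNA, ncRNA, promoter, gene body; piRNA type I/II
precede snRNA when a piRNA annotation is supplied. Promoters are the
500 bp upstream of protein-coding TSSs, strand-aware. Overlap counts
are peak-wise: a peak spanning two snRNA genes counts once (so k can
exceed K in pathological geometries; the test statistic then uses
min(k, min(n, K))). Peaks inside supplied exclusion regions (the piRNA
clusters) are dropped before classification, reproducing
outside-the-cluster analyses.

The hypergeometric universe is the consequential free choice. We use a
**size-aware locus universe**: every annotated locus contributes
`max(1, round(len / 300))` tiles to its class count K and to N, and
unannotated space contributes 300-bp pseudo-loci to N. Compact ncRNA
classes keep K = gene count, while a 2-kb gene body counts ~7 tiles —
in proportion to the territory a randomly placed peak could hit.
With raw locus counts instead, size-heterogeneous classes are
anti-conservative: a circular-shift permutation control (shift all
peaks by a random offset, reclassify, retest) gives median gene-body
p ≈ 0.03 under the null, versus ≈ 0.7 with the size-aware universe.
Both the universe and the tile width are configurable. Raw p-values
are reported (as −log₁₀ p) alongside BH-adjusted q over the
factor × class grid.

The upper tail is evaluated through `logsf` for deep-tail stability and
verified against exact integer enumeration for every parameter tuple
with N ≤ 30 (worst relative error < 1e-14).

## Profiles and quantification

Metaprofiles anchor on single bases (piRNA first-U or motif starts),
average unmasked track values per bin, and reverse minus-strand rows so
upstream is always left. Default geometry: ±500 bp at 50-bp bins for
motif-scale profiles, ±5 kb at 100-bp bins for heat maps (the exact
display binning of the original figures is not recoverable; these are
this package's defaults). Aggregation is the column-wise mean with
per-column n and standard error; all-missing bins stay missing.

Bin quantification tiles the piRNA clusters and each somatic chromosome
(I, II, III, V — X excluded by default, configurable) into 1-kb bins,
takes per-bin means of unmasked log2 signal, and summarizes per group
with a Tukey box (notch half-width 1.58·IQR/√n). Because notch overlap
is only a visual median test, a two-sided Mann–Whitney U test of
cluster bins against each somatic chromosome is reported alongside.

## Synthetic data

The generator emulates the study's design: a 200-kb cluster chromosome
("chrIV") carrying two 14-kb piRNA clusters, four 100-kb somatic
chromosomes, 40 type I piRNA genes, 12 type II, and
snRNA/snoRNA/tRNA/miRNA/lincRNA/protein-coding genes on the somatic
chromosomes. Type I genes carry the literal `CTGTTTCA` ending 40 bp
(configurable; the real spacing is not standardized) upstream of the
first-U on the coding strand and a `YRNT` word whose T is the first U;
minus-strand genes plant reverse complements on the reference. One
low-mappability decoy (mappability 0.1) exercises masking; two planted
input-artifact regions (input and ChIP jointly inflated 50×) exercise
blacklisting.

**Cluster geometry.** Type I genes sit on a jittered regular grid
(~700-bp spacing, jitter ≤ 50 bp), emulating the dense, fairly even
spacing of the natural clusters. The spacing matters: promoter
enrichments must be dense enough that 1-kb cluster bins rise ≥ 1 log2
unit above somatic background, yet far enough apart that neighbouring
peaks stay resolvable at a 150-bp fragment size. Random placement
cannot satisfy both at once.

**Coverage model.** Background coverage is piecewise-constant over
50-bp windows, drawn from a negative binomial with mean = depth
(default 30) and dispersion α = 0.1 (var = m + αm²) — overdispersed,
as real ChIP input is. Enrichment is shaped as fragment pile-up around
the bound element: full fold (default 8) across the element core (Ruby
motif through first-U for type I promoters; the TSS base for type II
and snRNA/snoRNA), tapering linearly to 1 over 1.5 fragment lengths on
each side, approximating the spread of a sonicated fragment-size
distribution. A flat enrichment plateau would instead make the
aggregated profile's maximum a coin flip across the plateau.
Replicates differ only by sub-seed; all outputs are bit-reproducible
from (spec, seed).

**What the synthetic tests do not show.** The generator has uniform
base composition (no GC bias), piecewise-constant noise (no
fragment-level autocorrelation), no duplicate-read artifacts, and
planted elements are exact motif copies. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's logic
under the study's signal structure — not performance on real libraries,
where normalization quality and blacklist completeness depend on biases
this simulation deliberately omits. Published genome-scale counts
(e.g. blacklist region totals against real input libraries) depend on
the deposited data and are out of scope here.

## Problem sizes and determinism

The bundled study is a 600-kb genome, five factors (including the
fold-1 control) × two replicates + input at 1-bp track resolution —
small enough that the full pipeline runs in seconds while every stage
operates at realistic per-base granularity. All randomness flows from
a single integer seed through `numpy.random.default_rng`; two runs with
the same seed produce byte-identical text outputs, which the test suite
and the acceptance script verify by hashing.
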