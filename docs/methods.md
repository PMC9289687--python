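# Methods

## Scope and model

`ploidymeth` analyses per-cytosine bisulfite count data from two
cytotypes of one genotype (a diploid "2x" and a derived
autotetraploid "4x"), in the three plant methylation contexts CG,
CHG, and CHH (H = A, T, or C). The pipeline covers:

1. context assignment from the reference sequence;
2. methylcytosine calling by a one-sided binomial test against the
   combined non-conversion/sequencing error rate ε, with
   Benjamini–Hochberg FDR control;
3. weighted methylation levels, Σ n_meth / Σ n_total over a region's
   cytosines;
4. metagene profiles over scaled feature bodies with fixed 2-kb
   flanks;
5. sliding-window DMR detection between cytotypes;
6. association analyses between transposable-element (TE) proximity,
   methylation, and expression.

A synthetic-data generator with planted ground truth drives all
recovery tests; it is first-class, tested code.

All coordinates in memory are 0-based half-open. GFF3 (1-based
inclusive) is converted on read, BED passes through.

## Methylcytosine calling

For a cytosine covered by `n_total` reads of which `n_meth` support
methylation, the null is that every methylated read is error:
p = P(X ≥ n_meth | Binomial(n_total, ε)). ε defaults to 0.005
(conversion > 99%) and can be estimated from an unmethylated control
sequence as its pooled weighted level. BH correction is applied
*within each context class*: the genome-wide CHH base rate is an
order of magnitude below CG, and pooling contexts would let the CG
signal mass distort the CHH null. Sites with coverage below 4 are
left uncalled rather than called unmethylated. Symmetric CG pairs
are kept as two per-strand records (the least destructive default);
`merge_cg_strands` combines a pair's counts when a single record per
CG dyad is wanted.

Context assignment is strand-aware and lazy: a CG call needs only
the next base 5'→3' on the cytosine's strand, CHG/CHH need two. A
needed base that is missing (sequence end) or N yields "undefined",
and such cytosines are excluded from every denominator.

## Weighted levels and profiles

The weighted level is read-weighted, not site-averaged: two sites
0/10 and 10/10 give 0.5. It is undefined (NaN) — distinct from 0 —
when no reads remain, and is invariant to record order and to
splitting a region and pooling counts.

Metagene profiles use 20 upstream and 20 downstream 100-bp flank
bins plus 20 equal-width (percentile) body bins; bodies shorter than
the bin count are skipped and counted. Minus-strand features are
binned by distance from their own 5' end, so a mirrored layout
reproduces the profile exactly and flipping only the strand
annotation reverses it. Per-bin values pool raw counts across
features (matching the weighted-level definition); a
mean-of-feature-means estimator is available and is used wherever
*groups of genes* are compared (expression-group stratification),
because pooled counts let one long TE-rich gene dominate a group.
Profile pairs are compared with a paired two-sided t-test over bins
(bins undefined in either profile dropped); an exactly constant
nonzero difference has zero variance and is flagged degenerate with
p reported as 0 (< 1e-10). Whether such comparisons should be over
bins or over features is an open methodological point; bins were
chosen and this is a known limitation.

## DMR detection

Windows of 200 bp at 100-bp step are tiled per chromosome (the
window geometry is exposed as configuration). Within a window and
context, only cytosines with pooled coverage ≥ 4 in *both* cytotypes
at shared positions are used — the shared-position requirement
prevents coverage-composition artifacts. A window is tested when it
holds at least the context minimum of such sites (allC 20, CG 5,
CHG 5, CHH 15 — plausible counts for ~200 bp of a plant genome); the
test is Fisher's exact on the pooled 2×2 table
[n_meth, n_unmeth] × cytotype, BH-corrected across all tested
windows of that context. Windows pass with |Δ| ≥ 0.25 (0.20 for
allC) and q ≤ 0.05. Overlapping or book-ended significant windows
of equal direction merge into maximal DMRs; ratios are recomputed
over the union and the minimum q kept. A merged region whose
recomputed |Δ| falls below the threshold is discarded so that every
reported DMR honours the effect-size contract (a rare edge when
adjacent windows pass individually in opposite tails of the
union). Direction is the 4x level relative to 2x (hyper/hypo).
Replicates are pooled per cytotype before testing; a per-replicate
sign-consistency filter is available but off by default.

Annotation assigns each DMR by base-pair majority among overlapped
feature kinds with ties broken PCG > lncRNA > TE; no overlap is
intergenic. The gene-flank flag marks DMRs whose midpoint lies
within 4 kb of a PCG/lncRNA interval (inside included).

## TE association

Distances are gaps between half-open intervals: 0 on intersection
and for book-ended intervals; the body-overlap flag requires true
intersection. Flank TE counts deduplicate TEs spanning both flanks
and exclude body-only TEs. Expression groups follow the
threshold-plus-tertiles scheme: mean FPKM < 0.1 is "none"; the rest
are ranked and split into equal thirds (remainders to the lower
groups) — a genuine four-quantile split cannot accommodate a zero
class of arbitrary size. Group tests are Welch's t or the two-sided
rank-sum test (exact enumeration for combined n ≤ 20 without ties,
normal approximation with tie correction otherwise). TE methylation
by distance pools TE-body cytosine counts into 500-bp distance bins
up to 8 kb from the nearest anchor feature.

## The synthetic-data generator

The generator emulates a TE-dense plant genome: random sequence at
36% GC; 55 protein-coding genes and 22 lncRNAs per Mb with
non-overlapping bodies (lognormal lengths); TEs placed until their
union covers 60% of the sequence, overlapping gene bodies with
probability 0.3, drawn from an order mixture dominated by Gypsy and
Copia. lncRNAs at least 2 kb from every gene are flagged lincRNA.

True methylation probabilities combine stratum baselines
(TE body by order ≫ lncRNA region > intergenic > PCG region, per
context) with a metagene shape: cosine-ramped body multipliers give
PCGs a CG body peak (amplitude 1.6) and a CHG/CHH body dip
(amplitudes 0.25/0.30), lncRNAs mildly elevated bodies. Baselines
were calibrated once so the genome-wide weighted levels land near
mCG 0.67, mCHG 0.49, mCHH 0.06; per-stratum truths beyond the
genome-wide levels are qualitative and all user-overridable.

A per-gene latent activity a ~ N(0,1) couples methylation and
expression. Body CHG/CHH probabilities are scaled by
0.4 + 1.2·σ(c·a) with c = −1 for PCGs and +1 for lncRNAs; the factor
applies to **every body cytosine, TE-derived included**, because in
a 60%-TE genome the gene-body non-CG signal is carried mostly by
body TEs — coupling only the non-TE fraction leaves group-level
ordering statistically invisible at desk scale. The factor has unit
mean over genes, so genome-wide calibration is unaffected.

Observed data: depth per cytosine is negative-binomial (mean 30,
dispersion 5), mimicking uneven WGBS coverage and exercising the
coverage-≥4 filter; uncovered cytosines are emitted with zero
counts. Methylated counts are Binomial(depth, p(1−ε) + (1−p)ε) with
a single symmetric ε = 0.005 folding failed conversion and
sequencing error together. One global seed expands into
per-(cytotype, replicate, chromosome) PCG64 substreams, so outputs
are byte-identical per seed and independent of iteration order.

Planted DMRs are intervals chosen to contain at least the minimum
number of context sites their detection criteria require (so every
plant is detectable in principle); inside them the 2x probability
becomes a base value (0.25 for hyper, 0.75 for hypo) and the 4x
probability is offset by the signed Δ. The truth record carries the
planted intervals, per-cytosine probabilities per cytotype, and the
expression coefficients, and suffices to score sensitivity and FDR.

Expression: log10 FPKM = kind intercept + s_prox·exp(−d/1 kb)
+ s_count·(TEs in 4-kb flanks) + 0.8·a + N(0, 0.45), with
s_prox = −1.5, s_count = −0.08 for PCGs and the opposite signs for
lncRNAs; replicate noise sd 0.05 in log10. The slopes are strong
and the kernel short-ranged by design: in a 60%-TE genome
nearest-TE distances are compressed toward zero, and the encoded
relationships must dominate noise to be recoverable from a few
hundred genes per run. The configured "none" fraction (25% of PCGs,
35% of lncRNAs) is assigned to the features with the lowest latent
expression and set to FPKM 0, so silent features coincide with
TE-dense, low-activity ones.

What the generator does *not* emulate: read-level data (no FASTQ),
pericentromeric level gradients, strand-asymmetric methylation,
subcontext (CAA vs CAT) structure, allele-specific methylation,
aneuploidy, or any real linkage between the 2x and 4x genomes
beyond shared truth. Passing recovery tests therefore demonstrates
correctness of the estimators and detectors under the stated
sampling model, not performance on real WGBS libraries.

## Problem sizes used by tests and the acceptance script

Null calibration of the caller uses 1e5 sites at depth 30; level
recovery uses a 1.6-Mb featureless genome (≥ 1e5 CG sites); DMR
recovery a 2-Mb genome at 30× with 20 planted CG DMRs (Δ = 0.4,
≥ 10 CG sites each); direction recovery a 6-Mb genome (~330 PCGs,
~130 lncRNAs). These sizes give the planted effects comfortable
statistical margins while keeping a full run in minutes on one
core.

## Numerical choices

Fisher p-values are cached per 2×2 table within a run. BH is always
per context (calling and DMR testing alike) — the source thresholds
name only q ≤ 0.05, and per-context correction keeps the mixture of
base rates from distorting any one context's null. Profile
comparison treats diffs with relative range below 1e-9 as constant.
Expression-group ranking breaks FPKM ties by feature id for
determinism. Nearest-TE ties break by lower TE start, then id.
Chromosome-edge flank bins simply receive the cytosines that exist.
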