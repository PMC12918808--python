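# Methods

## The measurement

A FRep-Seq screen couples CRISPRi knockdowns to barcoded reporter
transcripts and asks how each knockdown shifts the reporter between a
condensate-enriched pellet (20,000 g) and total lysate. The analysis
problem is to turn barcode x sample count tables into calibrated per-gene
effect sizes, despite (i) several orders of magnitude of barcode abundance
spread, (ii) count-noise variance that depends strongly on abundance, and
(iii) sample-to-sample depth differences.

## Normalization and the depth gauge

Per-sample scale factors use the median-of-ratios estimator: the reference
is the per-barcode geometric mean across samples (computed over barcodes
nonzero everywhere; below 50 such barcodes the estimate falls back to
total-count scaling), and factors are reported with geometric mean 1.

Median-of-ratios factors are only defined up to a common scale, and two
downstream constants — the pseudocount and the minimum-abundance filter —
are expressed in counts. The pipelines therefore pin the gauge: factors are
multiplied by (geometric mean of sample column sums) / `reference_depth`,
with `reference_depth` a fixed configuration constant (2e5 for screens, 2e6
for transcriptomes — the nominal per-sample depth). Normalized counts then
live on a stable count scale, and rescaling any single sample's raw counts
by a constant is absorbed *exactly* by its own factor: every NNS and
condensation z-score is invariant to floating-point accuracy. With purely
relative (geometric-mean-1) factors this invariance would be broken through
the pseudocount, because scaling one of *m* samples leaks a factor
c^(1/m) into every normalized count.

## The neighborhood-normalized score

For each replicate's pellet/total pair:

1. `log_ratio = log2((pellet/sf_p + c) / (total/sf_t + c))` with
   pseudocount `c = 0.5` (symmetric; keeps zero-pellet barcodes finite and
   strongly negative).
2. The **reference abundance** is the arithmetic mean of the two normalized
   counts. A symmetric function of both fractions is essential: filtering
   or ranking on the denominator alone conditions on its lower tail being
   absent, which skews the null log-ratio distribution left (we measured a
   persistent mean NNS of about -0.03 to -0.055 and non-uniform gene
   p-values with a total-only reference; the symmetric reference restores
   mean ~0, skew ~0 and uniform p-values).
3. Barcodes below `min_count = 20` normalized counts are dropped — their
   ratios are Poisson-noise dominated.
4. Survivors are sorted by reference abundance (ties broken by barcode for
   determinism). Each barcode's neighborhood is a symmetric window of
   `window = 201` barcodes in this ordering, truncated at the array ends.
   Location is the window median; scale is 1.4826 x MAD floored at 1e-8
   (the floor only bites when a window is exactly constant, where the
   numerator is zero anyway). `nns = (log_ratio - location) / scale`.

Median/MAD were chosen over mean/sd for robustness to the heavy-tailed
outliers genuine hits produce; the window size trades locality against
estimator noise (201 barcodes keep the scale estimate within a few percent
while tracking the abundance-dependent variance). Window size, filter,
pseudocount and estimators are all exposed as arguments.

## Gene scores and replicates

Guide score = unweighted mean of the guide's surviving barcode NNS; gene
score = unweighted mean over guides with at least one surviving barcode
(count-weighted means and medians are available via `guide_agg`/`gene_agg`;
the data do not determine a unique choice and the unweighted mean is the
default). Replicate gene scores are combined with a two-sided one-sample
t-test against zero (df = n-1). Degenerate cases are explicit: fewer than
two replicate scores gives no p-value (`insufficient_replicates`); zero
replicate variance floors the p-value at 1e-12 (`zero_variance`) rather
than reporting 0. Whether published FRep scores are means of per-replicate
NNS or an NNS of pooled counts is not decidable from the available
description; this implementation uses mean-of-replicates, which is what the
replicate t-test framing implies. Control-guide flags are carried through
but unused by default.

## Screen comparisons

Two screens are compared over shared genes by Pearson correlation of FRep
scores, plus per-gene conditional-interaction labels with `hit_threshold=2`
(echoing the FRep > 2 hit convention) and `delta_threshold=1`: `shared`
(hit in both), `aggravating` (rises by >= delta into hit range in screen B),
`alleviating` (the mirror case), else `neither`; precedence in that order.

## Temporal classification

Trajectories of FRep scores at 0/10/30/60 minutes of heat shock are
classified by threshold rules: sustained (> 2 everywhere), basal (> 2 at 0
min and < 3 at every heated timepoint — the asymmetric cap is kept verbatim
and is configurable via `basal_cap`, since a cap of 2 is the other
defensible reading), early (< 2 at 0, > 2 after), time-dependent (all three
consecutive differences > 0 and > 2 at 60 min — "difference between time
points" is read as every consecutive pair including 0 to 10, matching the
additive-over-time interpretation). The printed rules overlap, so labels
are assigned with precedence sustained > basal > early > time_dependent,
preferring the stronger phenotype; the precedence is an argument. All
comparisons are strict, so boundary scores such as (2,2,2,2) fall to
`other`. The classifier is a total, pointwise function: a gene's label
never depends on other genes.

## Fractionation RNA-seq

Condensation score = normalized log2(pellet/total) per transcript and
condition; ribosome-association score = the same with the ribosomal
fraction. Replicate columns are pooled by summation before scoring. A
direct normalized ratio is used rather than an interaction-model fit: the
downstream quantities are ranks and group contrasts of the pellet-vs-total
log2 ratio itself, and an explicit estimator keeps the computation fully
specified.

Because longer transcripts partition into condensates regardless of stress,
scores are standardized within bins of 100 length-sorted transcripts (ties
broken by transcript id; a final partial bin of fewer than 10 transcripts
is merged into the previous bin to avoid unstable standard deviations; a
zero-variance bin yields z = 0 with a flag). Binning is by length only, so
both conditions share one partition, and z-scores are computed per
condition within it; delta condensation = z(42C) - z(30C).

Group contrasts use the two-sample Wilcoxon rank-sum (Mann-Whitney U) test
of each annotated group against the background transcriptome, two-sided,
with the normal approximation and tie correction — except when both groups
have <= 12 members and no ties, where the exact null is enumerated.
p-values are Bonferroni-multiplied by the number of tested groups and
capped at 1.

## qPCR -ddCt

Each well's Ct is the median over its technical replicates. For a target
in one (condition, strain): dCt_f = Ct_target,f - Ct_reference,f for
f in {pellet, total}, and condensation = -(dCt_pellet - dCt_total) — log2
pellet enrichment of the target relative to the reference gene (ACT1 by
default); +1 means 2-fold enrichment. Optionally values are re-expressed
relative to a reference strain, with the linear fold 2^difference reported
alongside. Missing wells fail loudly with the (target, condition, strain)
named.

## Barcode counting

Reads are `flank5 + barcode + flank3`. The 5' flank is located by a
leftmost-wins scan allowing `max_flank_mismatch = 1` substitutions; the
following fixed-width window is assigned to the unique library barcode
within Hamming distance `max_mismatch = 1`. If two or more barcodes
qualify the read is dropped as ambiguous — never fractionally assigned;
generated libraries enforce pairwise distance >= 3, which makes
one-mismatch assignment provably unambiguous. N bases count as mismatches.
Reads are used untrimmed: barcodes are short, anchored, and quality
information adds nothing to a Hamming decision. QC partitions every read
into exactly one of assigned / ambiguous / unmatched / no-anchor. For
mismatch budgets <= 1 matching uses a precomputed variant table with
semantics identical to the per-read search (covered by an equivalence
test); counting streams with constant memory.

## The synthetic-data generators

The screen generator emulates the stated design: ~12 guides per gene, 2
barcodes per guide (the true barcode multiplicity is only stated as "more
than one"; 2 is this package's choice), 4 biological replicates, 2e5
expected reads per sample. Barcode abundances are log-normal (sigma = 1,
heavy-tailed, as pooled libraries are); counts are negative-binomial with
variance mu + 0.05 mu^2. Planted modulators (default 5% of genes, +1.5
log2) multiply **pellet means only**, leaving total-fraction expression
untouched — condensation effects are partitioning effects, not expression
effects. Per-gene, per-replicate log2 jitter (sd 0.1) models biological
replicate wobble. All randomness derives from one seed through fixed
per-operation substream labels, so identical configs give bit-identical
tables and FASTQ bytes regardless of call order.

The transcriptome generator draws 5000 transcripts with log-normal lengths
(median ~1.1 kb) and models log2(pellet/total) as baseline(condition) +
1.2 x centered log2 length + group effect + a stable per-transcript
propensity (sd 0.7) + condition noise (sd 0.5). Group labels cover 2% each
of Hsf1-regulon, Msn2/4-regulon and ribosomal-protein-gene transcripts
(exactly 100 per group at n = 5000). At 42C the planted shifts are RPG +1,
Hsf1 -1, Msn2/4 -0.5 log2 on condensation; +1.5/-1.0/+0.5 on ribosome
association; and transcriptional induction of the stress regulons on
expression. These magnitudes give the qualitative heat-shock structure —
RPG transcripts condense and leave ribosomes, heat-induced transcripts
decondense and stay translated — at comfortably detectable effect sizes for
100-transcript groups.

The Ct generator models Ct = intercept (38) - log2(abundance) + N(0, 0.2)
with three technical replicates per well.

What the generators do **not** emulate: PCR amplification bias and UMIs,
indel sequencing errors, guide-efficiency heterogeneity, batch effects,
fraction cross-contamination, and any real regulon annotation (group labels
are synthetic stand-ins for Hsf1/Msn2-4 target lists). Passing tests
therefore demonstrate that the estimators are correct and calibrated under
a realistic count model — not that real screens are free of these
additional error modes.

## Problem sizes and runtime

The reference conditions used throughout the tests and the acceptance
script — 300 genes x 12 x 2 barcodes at depth 2e5, 5000-transcript
transcriptomes, ~1e5 simulated reads — run the full pipeline in seconds on
one CPU while leaving all statistical checks well-powered; they are the
package's standard demonstration sizes.

## Known limitations

* Gene aggregation is unweighted; very-low-count surviving barcodes get
  full weight (mitigated by the abundance filter).
* The t-test treats replicate gene scores as exchangeable normals; with 4
  replicates mild tail deviations are absorbed, but 2-replicate screens
  yield only descriptive p-values.
* The neighborhood window is truncated (not shifted) at the abundance
  extremes, so the ~100 most and least abundant barcodes are standardized
  against asymmetric neighborhoods.
* Cross-screen comparison assumes score scales are comparable, which holds
  when both screens were scored by this pipeline at similar depth.
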