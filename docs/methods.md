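# Methods

`lineamp` implements an integrative copy-number / expression analysis for
discovering lineage-specific amplicon driver genes: given tiling-path
array-CGH profiles for two tumor cohorts of different histology and matched
expression data, it finds genomic regions whose alteration pattern is
specific to one lineage, and filters the genes inside them through a cascade
of dosage-association and expression criteria until (ideally) a single
candidate driver remains. This note documents the model, the defaults, and
the choices made where the design was open.

## Per-sample aCGH processing

**Replicate QC.** Each clone (tiling array element) carries replicate log2
ratio spots. A clone is removed when its replicate standard deviation exceeds
`max_replicate_sd` (default 0.075) or its signal-to-noise ratio falls below
`min_snr` (default 3). Removed clones keep their genomic position and are
flagged missing; the combined ratio of a retained clone is the arithmetic
mean of its replicates (the conventional combination rule; the upstream
two-channel normalization that produces these ratios is out of scope).

**Segmentation.** Profiles are fit per chromosome by exact dynamic
programming minimizing

    total within-segment SSE + lambda * scale * (#breakpoints),

with the breakpoint count capped (default 100 per chromosome). `lambda`
(default 6.75) is a dimensionless smoothness knob; `scale` defaults to
`"auto"`, the per-clone noise variance estimated robustly from successive
differences (1.4826 · median |Δ| / √2, squared). The auto scale makes the
penalty track the data's noise level, so the same `lambda` behaves
consistently across noise regimes; setting `scale=1.0` gives the absolute
SSE-units objective, which is what the exhaustive-enumeration oracle tests
exercise. The DP is exact: for small inputs it provably returns the same
breakpoints as enumeration of every breakpoint placement. Two tie-breaks:
missing clones belong to the covering segment, with runs of missing clones
between two segments attached to the left segment; and among equal-cost
partitions the DP prefers fewer/earlier breakpoints.

**State calling.** Segment means above `gain_threshold` (+0.2 log2) are
called gain (+1), below `loss_threshold` (−0.2) loss (−1), otherwise neutral.
The external smoother the design replaces does not publish its
mean-to-state rule, so the thresholds are explicit configuration; ±0.2 is a
conventional choice between the single-copy-gain expectation (~+0.58 in pure
tumor) and typical tumor-content attenuation.

**High-level amplification.** A maximal run of ≥2 consecutive, non-missing
clones with combined log2 ratio above the threshold (0.6 for tumors, 0.8 for
carcinoma-in-situ lesions, which carry more contaminating normal cells) is an
amplicon. Runs never bridge missing clones — conservative, since bridging
would invent data. The caller operates on raw combined ratios by default
(segment means can be passed instead); raw ratios preserve focal events that
smoothing might average away. The group amplification score counts, per
clone, the samples whose amplicons cover it.

## Two-cohort disparity analysis

States are compared between cohorts A and B clone-by-clone after three
preparation steps:

1. **Imputation**: a missing entry takes the state of the nearest non-missing
   clone of the same sample within 10 Mb. If the two nearest neighbours are
   exactly equidistant, an agreeing state is used and a disagreement yields
   neutral. (Forcing neutral on agreeing ties would contradict the
   nearest-wins principle, so agreement wins.) Imputation is idempotent and
   never changes observed entries.
2. **Aggregation**: within each cohort, a boundary is placed between adjacent
   clones whenever fewer than 90% of that cohort's samples agree in state
   across the pair (pairs with a missing member are excluded from the
   denominator). The two cohort partitions are intersected (union of
   boundaries), so no region mixes clones that either cohort considers
   heterogeneous.
3. **Representative state**: each sample's state in a region is the majority
   state of the member clones (ties → neutral). This reduction is needed to
   build one 3×2 table per region; the alternative (testing each clone and
   summarizing) is noted but not used, and every reported region carries its
   full contingency table for audit.

Each region's gain/neutral/loss × cohort table is tested with an exact 3×2
Fisher test — the sum of multivariate hypergeometric probabilities of all
tables with the observed margins no more probable than the observed one
(enumerated over the free first column; verified against full enumeration and
against R's `fisher.test`). Benjamini-Hochberg correction runs over the
number of distinct regions; regions with adjusted p ≤ 0.01 survive. Adjacent
surviving regions within 1 Mb agreeing in direction (the altered state with
the largest absolute between-cohort frequency difference, and which cohort
carries the excess) are merged, and merged statistics recomputed. Finally a
region must be altered — direction-specifically — in >20% of one cohort with
a between-cohort difference >10%. Direction-specific interpretation of
"altered" matches the directionality of the merge rule; a flag could widen it
to gains+losses combined but the default is the narrow reading.

## Dosage–expression integration

**Differential expression** between cohorts uses a one-tailed Mann-Whitney U
test per probe (exact null distribution when the pooled sample count is ≤20
and tie-free, otherwise the normal approximation with tie and continuity
corrections), BH-corrected over all tested probes at α = 0.01. Multiple
probes per gene collapse to the lowest-p probe (or the highest mean-intensity
probe, for intensity-scale platforms).

**Method 1 — windowed Z-score correlation.** Each sample's combined ratios
are averaged over 10-kb windows tiling the chromosome from position 0
(clone values weighted by base-pair overlap), then Z-transformed with the
sample's own genome-wide mean and SD. A gene's dosage is the average Z over
the windows overlapping its interval; Spearman's rho against the gene's
log10 expression across samples is tested one-tailed for positive
correlation (exact permutation null for n ≤ 7 tie-free, t-approximation
otherwise), BH-corrected at α = 0.01. A sample whose profile has no variance
has no defined Z-score and is rejected. Note the standardization is per
sample, so cross-sample ranks are not those of the raw windowed means; the
recipe is applied literally.

**Method 2 — gain-versus-neutral group test.** A gene's categorical dosage
status per sample is the majority segmentation state of its overlapping
clones. Expression in gain/amplified samples is compared against
copy-number-neutral samples (loss samples excluded, their count reported) by
one-tailed Mann-Whitney, BH at α = 0.05, and the association additionally
requires both the median and the mean of the gain group to exceed the
neutral group's.

**Tumor-versus-normal elevation.** Fold change is the ratio of group medians
on the linear scale (inputs exponentiated according to the declared scale;
medians are robust and the estimator is otherwise unspecified in this kind of
design), with a one-tailed Mann-Whitney p for tumor > normal.

## The candidate cascade

A candidate driver must pass all five criteria: (1) lie inside a disparity
region; (2) be differentially expressed toward the gained cohort (BH ≤ 0.01);
(3) show Spearman dosage correlation rho > 0.75 at BH ≤ 0.01; (4) show the
gain-versus-neutral elevation (BH ≤ 0.05 plus both guards); (5) be elevated
≥2-fold over normals at BH ≤ 0.01. Criteria 3 and 4 are applied as a
sequential AND — the two integration methods are complementary, and a gene
must satisfy both. The fold threshold is 2 with the module α; the very small
p observed for a real driver is an outcome, not a cutoff, so it is recorded
but not enshrined. Genes failing exactly one criterion are reported as
near-misses with the failed criterion named; genes absent from any upstream
result set are reported untestable, never dropped. Early-event evidence
(amplification frequency in the CIS-like cohort at threshold 0.8) is reported
per candidate as corroboration, not used as a gate. The candidate set is
monotone: tightening any threshold can only shrink it.

## Expression signature (SAM)

For a chosen gene (its brightest probe by mean intensity), samples are sorted
and the top and bottom `n_extreme` (default 10) form two classes for unpaired
two-class SAM: d = (mean₁ − mean₂)/(s + s0) with the pooled standard error s.
`s0` defaults to the percentile-grid rule (choose the percentile of s that
minimizes the coefficient of variation of the MAD of d across s-quantile
windows); a fixed s0 is available for oracle tests. FDR at a symmetric |d|
cutoff is π₀ · (mean permuted count beyond the cutoff)/(observed count), with
π₀ estimated from the fraction of observed d inside the permutation
interquartile range; the q-value of a gene is the minimum FDR over cutoffs
that include it, so q is monotone in |d|. Permutations are balanced
(half-and-half) when group sizes are equal and even. Group order is
canonicalized internally so swapping the class labels exactly negates d and
preserves q. Defaults: 1000 permutations, q ≤ 0.05.

## Synthetic cohorts and what they do (not) show

The generator emulates the study design: a single 24-Mb chromosome arm tiled
by 300 clones of 80 kb; tumor cohorts AC (n=50) and SqCC (n=50); an
expression-only normal cohort (n=30); a high-heterogeneity preinvasive
cohort (n=20). Planted alterations, chosen to reproduce the structural
operating points of this class of study:

- telomeric loss 0–6 Mb in 39% of AC and 30% of SqCC (a frequent-but-shared
  event whose 9-point difference exercises the >10% filter);
- the driver gain 9.0–11.5 Mb in 40% of SqCC vs 5% of AC, with 30% of
  carriers boosted to amplification level (≈12% of the cohort);
- a gain 17–19 Mb shared equally (40%/40%) by both cohorts — altered but not
  lineage-specific;
- amplification of the driver locus in 7/20 of the preinvasive cohort.

Carrier counts are exact (`round(fraction · n)`, random membership), so
frequencies are reproducible; each carrier's shift is attenuated by a
uniform multiplier in (0.75, 1.25) standing in for tumor-content and clonal
heterogeneity. Every genome additionally receives three random ±0.3 log2
passenger segments of 1.6 Mb placed outside the planted regions: realistic
for tumor genomes, and necessary so that the per-sample Z-transform is well
defined even in noise-free runs. Replicate spots are Gaussian around the true
segment level with SD 0.04 (a free parameter — the platform's real spot noise
is not published; 0.04 keeps the natural replicate-SD rejection rate at the
0.075 cutoff around 3%), and 2% of clones per sample are injected with
inflated replicate noise or sub-threshold SNR to exercise QC.

Expression (log10 ratio scale) is generated for a matched sub-panel —
34 AC and 13 SqCC, the SqCC subset stratified to 6 driver-region carriers —
mirroring the size and dosage composition of a realistic matched
CGH+expression panel; with many more uncoupled neutral samples the rank
correlation of even a perfectly coupled gene is bounded near 1 − q³ (q the
neutral fraction), which is the relevant small-panel operating regime for
the rho > 0.75 criterion. The driver gene is elevated by 0.6 log10 in SqCC
and coupled to true dosage with slope 1. The decoy panel violates one
criterion each: a gene in the shared (non-disparity) region; a gene whose AC
expression mirrors the SqCC distribution (not differentially expressed); a
gene whose carriers are elevated as a block but reverse-coupled within
carriers, with the top-dosage quarter placed just below the neutral block
(rank correlation collapses while the group test stays significant); a gene
with its lowest-dosage carrier expression-silenced far below baseline (the
group mean guard fails while the rank test, median guard and correlation
survive); and a gene equally elevated in normals (fold ≈ 1.3). Passenger
genes in the region follow the not-differentially-expressed pattern,
mirroring the many-probes → few-lineage-specific-genes narrowing.

Passing tests on these data show that the statistics, filters and plumbing
behave as specified under a Gaussian, piecewise-constant, single-arm model
with exchangeable samples. They do not validate performance under spatial
array artifacts, probe-specific biases, intra-tumor heterogeneity beyond a
scalar shift, multi-arm dependence, or non-Gaussian expression noise — all
out of scope here.

## Numerical and size choices

Exact tests switch to approximations at the documented sizes (MWU: pooled
n > 20 or ties; Spearman: n > 7 or ties). Fisher enumeration compares log
probabilities with a 1e-10 additive tolerance to absorb rounding. TSV floats
are fixed at six significant digits and all writes are atomic, so repeated
runs with one seed are byte-identical. The bundled statistical checks use the
study-design sizes (50+50 samples, 500-region null screens over 200
replicates, 100-seed recovery runs, 20-seed noise-free cascade runs) — sizes
at which every check completes in seconds to a couple of minutes on one CPU.

## Known limitations

Single-chromosome-arm simulation by default (multi-chromosome input is
handled by the per-chromosome segmentation, but the generator emulates one
arm); the per-region representative-state reduction is one of two defensible
readings of a per-locus test reported region-wise; the frequency filter's
"altered" is read direction-specifically; π₀ estimation in SAM is the simple
quantile rule, adequate for signature-sized panels but crude for very small
gene counts; the dosage status for the group test inherits segmentation
thresholds, so borderline gains (< +0.2 after attenuation) count as neutral.
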