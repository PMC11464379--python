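# Methods

This note documents the models implemented in `methstem`, the conventions
and defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.
Every empirical number mentioned here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Data model and coordinates

A cell's methylome is a sparse map position → (n_methylated, n_total) per
chromosome, one map per context (CpG for endogenous methylation, GpC for
NOMe-marked accessibility; the two are never mixed, and the coverage-file
reader rejects a context mismatch declared in the file header). Internally
all coordinates are 0-based half-open; Bismark coverage files are read and
written as 1-based inclusive, BED as 0-based. The per-site call value is
n_methylated/n_total — for single-cell bisulfite data almost every site is
a single read, so values are essentially binary.

## Ensemble smoothing

The reference methylation track is computed at every pooled site as the
tricube-weighted mean of all pooled calls within ±h:

w(d) = (1 − |d/h|³)³,  value(x) = Σ w(xᵢ−x)·mᵢ / Σ w(xᵢ−x)·tᵢ

with h = 1,000 bp for CpG and 500 bp for GpC. Weighting calls (not site
means) makes the smoother exactly mass-preserving: a constant input yields
the same constant, which the property tests assert to machine precision.
The tricube kernel is used everywhere a kernel is needed (ensemble track,
pseudobulk locus curves at 1,000 bp) for consistency; pseudobulk curves
smooth per-site *means* with unit weights, matching how locus plots average
cell groups.

## Shrunken mean of residuals

Per cell and region, with residual rᵢ = callᵢ − track(xᵢ) over the n
observed sites: value = Σrᵢ/(n+λ), λ = 1 pseudo-observation by default.
The shrinkage pulls sparsely observed regions toward 0 (the ensemble);
|value| < 1 whenever λ > 0, and the magnitude grows monotonically with n at
fixed mean residual. A region with n = 0 is *missing*, never zero. The
exact shrinkage formula of other implementations of this quantity is not
published; anyone needing bit-compatibility with a specific tool should
check λ and the denominator convention here.

## Variance scan

Windows of 2,000 bp (1,000 bp GpC) slide in 10 bp steps. Each cell with ≥1
observed site contributes its window mean residual; windows with ≥10
covered cells (configurable) and between-cell sample variance (n−1
denominator) ≥ 0.2 are flagged, and overlapping or book-ended flagged
windows merge into VMRs (peak variance = max over members; merging is
idempotent).

**The scan statistic is unshrunken** (shrinkage 0 in the scan only). The
between-cell variance of window means for a perfectly bimodal region where
a fraction f of cells sit at one level and 1−f at the other, gap g apart,
is f(1−f)·g² — at most 0.25. Shrinkage multiplies this by (n/(n+1))² per
cell (~0.85 at typical per-window coverage), which would push even perfect
bimodal regions below the conventional absolute threshold of 0.2 and make
the threshold coverage-dependent. Quantification keeps λ = 1. A corollary
worth knowing: at threshold 0.2 the scan can only see contrasts carried by
at least ~28% of cells (f(1−f) ≥ 0.2); regions differentiating a small
minority of cells are invisible to it by construction, as
`analysis/03_scan_vmrs.py` demonstrates on early-changepoint wave-1 regions.

## Differential scan (condition DMRs)

Same windows at step 100: per window with ≥6 covered cells in each group, a
two-sided Wilcoxon rank-sum test on per-cell window means (exact null for
tie-free combined n ≤ 25, tie-corrected normal approximation otherwise),
BH-adjusted over all tested windows at FDR 0.05; significant windows merge
into DMRs with the direction of the raw mean-methylation difference
(|difference| ≤ 1 by construction). Under exchangeable groups the realized
significant-window fraction stays within 3 Monte-Carlo standard deviations
of the FDR target (in practice ~0).

## Iterative missing-value PCA

Region matrices are mostly missing, so PCA proceeds by: (1) drop features
observed in < 20% of cells (40% for accessibility) — thresholds in this
range barely move the embedding; (2) centre each cell's observed values
(removes per-cell technical offsets such as global conversion-rate
differences); (3) fill missing entries with feature means; (4) iterate
rank-k SVD reconstruction → refill missing entries until the relative
Frobenius change of the imputed block is < 1e-4 (max 50 iterations,
deterministic — no random initialization). On complete data this is exactly
PCA (per-component |r| ≥ 0.999 against a direct SVD); on a planted rank-2
structure with 30% missingness the recovered subspace agrees to < 10°
principal angle. Components capturing technical quality can be excluded
downstream via an explicit exclusion list in the pipeline config — never
automatically.

## Step-function changepoint fit

Along integer pseudotime ranks, each region's methylation series is fit
with mean levels before/after a change point s, minimizing the sum of
squared residuals by exhaustive search over all admissible breakpoints
(between consecutive distinct ranks, ≥3 observations per side; prefix sums
make this O(n)). Ties in SSE break toward the smallest s; s is reported as
the midpoint between the flanking ranks; the fitted levels are the side
means. The improvement 1 − SSE_step/SSE_const ∈ [0,1] (with a round-off
guard so numerically constant series report 0), and a region is a
(de)methylation *event* when improvement ≥ 15% and the region is observed
in ≥ 100 cells. The 3-per-side minimum prevents degenerate one-cell levels;
the exhaustive optimizer matches brute-force enumeration exactly on random
series with missingness. Under planted steps (gap 0.6, Bernoulli site
noise) the median changepoint error is well under 10 ranks with ≥ 90%
event recall and ≤ 5% false events on constant regions.

Pseudotime itself is an input (ranks in cell metadata), as are cluster
labels; excluding lineages (e.g. oligodendrocytes) is a metadata filter,
not an inference.

## LMRs and the methylation score

VMRs covered in ≥ 30 cells per group are Wilcoxon-tested between groups on
shrunken residuals and BH-adjusted; adjusted p < 0.05 labels the region an
LMR of whichever group is hypomethylated (group A lower → astrocyte LMR by
the package's labelling convention). Swapping the groups provably flips
every label and difference sign and leaves p-values unchanged.

The methylation score uses *raw* mean methylation fractions (interpretable
0..1 scale): score = mean over astrocyte LMRs − mean over NSC LMRs, means so
that duplicating an LMR changes nothing. An astrocyte-like methylome (its
astrocyte LMRs unmethylated) scores negative; the state margin defaults to
0 (a hard sign split, matching a two-state read-out) and is exposed for
robustness analyses. Cells covering neither LMR set are flagged
indeterminate rather than scored.

## Expression coupling

Expression is log-normalized as counts scaled to 10,000 per cell, then
log1p. Nearest genes are assigned on gene *bodies* with signed distance
(negative upstream with respect to the gene's strand, 0 when overlapping),
ties to the first gene in sorted order. Correlations are two-sided Pearson
tests on pairwise-complete cells (≥ 5 required), BH-adjusted within each
feature family (VMR methylation, VAR accessibility, promoter methylation /
accessibility separately). The 2-Mb analysis deliberately correlates *all*
features within the window against each TSS's gene — not nearest-only — and
re-adjusts within that family before histogramming the TSS-strand-oriented
positions of significant pairs by correlation sign.

The TSS-downstream analysis quantifies the +2..+5 kb interval downstream of
each (stranded) TSS, tests methylation and expression differences between
the two groups (≥ 5 covered cells each, Wilcoxon, BH per read-out), bins
genes by methylation difference rounded to the nearest 10 percentage
points, and calls a gene NS when its adjusted methylation p > 0.05 or
|difference| < 5%. Marker genes per cluster are the top 100 by
log-fold-change of means among Wilcoxon-significant genes carrying a
gene-body VMR (the effect-size metric for "top" is a documented choice;
log-fold-change of means is used).

## Synthetic generator

The generator emulates the features of single-cell multi-omic bisulfite
data that the methods must survive:

- **Genome**: CpG sites with geometric spacing (mean 100 bp), an
  independent, disjoint GpC grid (mean 60 bp); non-overlapping planted
  regions (2 kb) placed in jittered slots with a ≥ 600 bp separation margin
  so regions stay resolvable at scan bandwidth.
- **Trajectory**: integer pseudotime ranks 1..n over contiguous state
  blocks astrocyte → qNSC → aNSC → TAP → neuroblast. Default occupancies
  (15/25/15/30/15%) loosely follow lineage composition; the bundled demo
  and analysis cohorts sample 35% astrocytes, reflecting astrocyte-enriched
  sorting and keeping astrocyte-vs-NSC contrasts above the scan's f(1−f)
  visibility floor.
- **Region classes**: astrocyte LMRs (low in astrocytes, stepping at the
  astrocyte/qNSC rank boundary), NSC LMRs (the mirror image), wave-1
  regions (change point in an early rank window, random direction), wave-2
  regions (demethylation in a late window — ranks 250–400 on the 540-cell
  reference scale, rescaled with cohort size), and trajectory-free bimodal
  regions. Default levels are near-binary (0.1/0.9 pairs; exactly 0/1 in
  the scan-validation cohorts), consistent with the essentially binary
  methylation of single cells.
- **Noise model**: each cell observes each site independently with a
  per-cell coverage fraction drawn uniformly from a configured range
  (default 0.25–0.6), and an observed site carries one Bernoulli call at
  the cell's true level. Bernoulli-per-site is the minimal model consistent
  with binary single-cell calls; no spatial correlation of coverage, no
  bisulfite conversion error, no doublets, no batch effects.
- **Promoters** are constitutively hypomethylated (level 0.1 within
  ±500 bp of every TSS) and accessible on the GpC layer — this is what the
  TSS-dip QC check and anchor profiles rest on.
- **Expression**: negative binomial with mean 20 and dispersion 2; coupled
  genes shift their log-mean by effect × sign × (level − ½) where level is
  the cell's true methylation of the linked gene-body region (sign −1:
  methylation silences). Coupled genes are laid out so the linked region's
  centre sits 3 kb downstream of the TSS, inside the gene body.
- **Determinism**: a fixed `SimConfig` (including seed) reproduces the
  dataset byte-for-byte; methylome, accessibility and expression draws use
  independent seed streams derived from the config seed.

What passing tests on this generator show — and what they do not: they
validate the estimators' operating characteristics (recovery, calibration,
error rates) under sparse binary sampling and realistic missingness. They
do not certify performance under features the generator omits: branched
trajectories (the linearized lineage places astrocytes before the NSC
states on one axis, whereas in tissue they are a side population),
covariance between coverage and cell state, region-size heterogeneity,
fragment-level correlation of neighbouring calls, or expression depth
variation between cells.

## Pipeline, sizes and runtimes

The pipeline config carries every threshold above as its default; unknown
keys are rejected, seeds are mandatory (no wall-clock), outputs carry a
config-hash/seed provenance header, and reruns are byte-identical. The
bundled demo runs a 240-cell, 2×2 Mb cohort (QC cutoffs scaled to that
genome: 4,000 sites, 10 genes — the analysis constants keep their standard
values) in well under a minute on one CPU. The validation studies use the
problem sizes at which their claims are stated: 200 series for optimizer
exactness, 500 regions × 500 cells for changepoint recovery, a 5-Mb genome
with 20 planted regions (plus a null genome) for the scan, 1,000 VMRs at
100 vs 100 cells for LMR calibration (the false-discovery proportion is
averaged over 5 replicate experiments, since FDR is an expectation and a
single realization carries Poisson noise of ±0.02 on ~5 expected false
positives), and 200-cell coupled cohorts for the expression analyses.
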