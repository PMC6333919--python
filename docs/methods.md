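# Methods

## The measurement model

In a hybrid (Cast × B6) cell line with doxycycline-inducible *Xist* on the
B6 allele, allele-resolved sequencing counts reads per feature (ChIP peak,
gene, or 10-kb window) per sample. The d-score
d = reads^B6 / (reads^B6 + reads^Cast) is the fraction of allele-assignable
signal on the future inactive X; it is an internally controlled ratio (the
Cast allele serves as the within-sample reference), so it needs no
between-sample normalisation. Repressive marks are the exception: their
enrichment on the active X is too low for a ratio to be stable, so gain is
quantified as normalised B6 counts relative to t = 0 instead
(accumulation), which *does* need between-sample scaling (TMM) and an
input-based window mask.

## Filters

- **Minimum allelic reads**: a feature is kept only if every sample has
  strictly more than `min_allelic_reads` allele-assignable reads — 50 for
  ChIP peaks, 10 for genes, 20 for FLAG peaks. Applied per sample (the
  stricter reading; configurable).
- **Biallelic at t0**: mean t = 0 d-score within [0.3, 0.7], closed
  interval ("comprised between" read inclusively; configurable bounds).
- **Replicate stability**: |d_rep1 − d_rep2| at every time point and clone
  must stay below median + 2 sd of all replicate differences pooled
  globally (pooling across time points, the plain reading of "all
  differences"). A 1e-12 epsilon keeps the degenerate all-equal case
  passing.
- **Escapees**: normalised d-score at 24 h ≥ 0.8 flags a feature as
  escaping (strict < retains).
- Features failing any filter are flagged, never dropped, so downstream
  counts are auditable.

## Normalisation

Normalised d-score: norm_d(t) = d(t) / d(0) / 2, so every retained feature
starts at 0.5 and full silencing approaches 0. The t = 0 denominator is the
pooled mean over replicates by default (per-replicate denominators are a
flag); pooling uses all information and keeps the t = 0 contract exact.

TMM scale factors follow the published defaults: M-values trimmed 30%
two-sided, A-values 5%, inverse-asymptotic-variance weights, reference
sample chosen by upper-quartile proximity to the mean. Two factor flavours
are exposed: the composition factor (geometric mean 1 — the convention of
edgeR's `calcNormFactors`, against which the implementation is
cross-checked in the test suite), and the effective scale factor (library
size × composition factor, anchored to the reference sample). Counts are
divided by the effective factor; anchoring to the reference sample means a
uniformly rescaled sample changes only its own factor, so accumulation
values of the other samples are untouched.

Input-outlier windows (accessibility/mappability bias) are masked when an
input sample's count leaves mean ± 1.5 sd, computed on the raw count scale
(log1p offered as an option).

## The LL.4 model and kinetic statistics

f(t) = c + (d − c) / (1 + exp(b(ln t − ln e))) — the drc LL.4
parameterisation: shape b, lower asymptote c, upper asymptote d, half-way
time e (hours). t = 0 is handled by the analytic limit (d for b > 0, c for
b < 0), not by a pseudo-time. All evaluations and both analytic
derivatives go through the logistic sigmoid of b(ln t − ln e), which is
overflow-free for any shape.

Fitting is bounded least squares (scipy `least_squares`, trf) on replicate-
pooled points (one fit per feature over all samples, e.g. 10 points for
5 × 2). Asymptotes are bounded to [0, 1] for d-score fits; accumulation
fits instead get loose data-driven bounds (±2–5 × the observed span) which
keep the optimiser off the degenerate straight-line ridge where d and e
diverge jointly. A 12-point multi-start grid (b₀ ∈ {0.5, 1, 2, 4} ×
e₀ ∈ time quartiles) takes the best SSR; on 10-point series this is cheap
(~50 ms/feature) and removes essentially all convergence failures.

- **IC35**: closed-form inversion t* = e((d − c)/(0.35 − c) − 1)^(1/b).
  0.35 is half of the observed 0.5 → 0.2 dynamic range of normalised
  d-scores; 0.25/0.30/0.40 are options. The inversion is verified against
  a 10,000-point grid search in the tests.
- **ED50**: reported as the e parameter. On the log-time axis the LL.4
  maximum-slope point is exactly e; on the linear axis the two differ
  slightly — e is the convention used here.
- **Onset**: extremum of the analytic second derivative, minimised (or
  maximised, for accumulation) on (ε, ED50) with ε = 1e-3 h to avoid the
  ln t singularity; restricting to below ED50 prevents landing on the
  symmetric extremum beyond the inflection. For shallow shapes (b ≤ 1) the
  curvature is monotone on the interval and the optimum sits on an
  endpoint; that is the correct constrained answer and is reported as-is.
- **Censoring**: any statistic beyond 24 h, or from a flat
  (d − c < 0.02), unconverged or undefined fit, is set to 24 h and
  flagged. Pairwise comparisons should use uncensored fits only.
- **Residual QC**: sum of squared residuals (the statistic behind the
  fixed 0.2 cutoff is an assumption; RMS is an option). Fixed mode:
  SSR < 0.2 (active marks). Adaptive mode: SSR < mean + 1.5 sd over the
  fitted batch (accumulation), with the same degenerate-equal epsilon as
  the stability filter.

## Corrections

**XO contamination.** Cultures that accumulate XO cells (one X lost) bias
the input's allelic composition. With p the input B6 fraction and
nf = p/(1 − p), each d-score is remapped d′ = d/(d + nf − nf·d). This is a
strictly increasing bijection of [0, 1] with inverse given by 1/nf; a
feature observed exactly at the input fraction corrects to 0.5. The
adjustment is applied to all samples sharing the flagged input. The
simulator uses the inverse map as the forward contamination model, so
correction round-trips by construction plus binomial noise.

**Incomplete induction.** When only a fraction q of cells induce *Xist*
(FISH cloud counts), the apparent dox/no-dox logFC is diluted by q. The
no-intercept model signal ~ 0 + clone + clone:induction (induction = 0 for
no-dox samples, q for dox samples) estimates per-clone slopes that equal
the logFC of a fully induced population. Fitting is OLS — a deliberate
simplification of the precision-weighted (voom) regression: with one
dox/no-dox pair per clone the slope equals the two-point extrapolation
(signal_dox − signal_nodox)/q regardless of weights, so weights affect
only standard errors. Per-clone slopes are reported individually plus an
unweighted mean. Fractions supplied as percentages (> 1) are divided by
100 with a warning.

## Classification

1-D k-means (scikit-learn, 10 restarts, fixed seed) with labels assigned
by centroid order, so they are invariant to input order and to k-means
label permutation: ascending IC35 centroids give early / intermediate /
late; descending sensitivity scores give sensitive / intermediate /
resistant. Centroid ties break by cluster size (larger first). Fewer
distinct values than clusters collapses to one label with a warning;
n < k raises. The sensitivity score is
Δ = (mut₂₄ − WT₂₄)/(WT₀ − WT₂₄) on normalised d-scores: 0 = silences like
WT, 1 = fully blocked. Features with zero WT dynamic range get nan and are
excluded from clustering.

Feature association compares early vs late groups per numeric feature with
a two-sided Wilcoxon rank-sum test, Benjamini–Hochberg adjusted across the
feature panel (per comparison); *Xist* entry-site proximity is the binary
flag distance < 100 kb, tested the same way.

## Interval conventions

0-based half-open everywhere (BED native); refFlat starts are 0-based per
UCSC. TSS is strand-aware (txEnd − 1 on the minus strand). Promoters are
TSS ± 2 kb clipped at chromosome bounds; gene bodies drop the first 2 kb
downstream of the TSS (strand-aware); enhancers are merged
H3K27ac ∩ H3K4me1 regions whose nearest-TSS edge distance is ≥ 1 kb
(against all transcripts by default; configurable); intergenic 10-kb
windows exclude any gene extended by its 2-kb promoter side plus active
enhancers. Consensus peaks support both published designs under one
operation: merge-then-intersect across replicates, or ≥ k-of-n coverage
(the FLAG design, k = 2 of 4), with the fold-change ≥ 3 pre-filter.
Distances are measured feature-midpoint to nearest anchor edge (the
convention is documented because the source procedure leaves it open);
densities are the covered-base fraction of a 100-kb window centred on the
feature midpoint. Everything is verified against per-base boolean-array
oracles on toy chromosomes, including minus-strand mirror tests.

## FISH profile quantification

Per-cell 1-D traces are consumed as already-extracted tables; axis drawing
and z-slice selection are upstream manual steps. The *Xist*-cloud boundary
is the pixel of minimum slope after a 3-px edge-padded moving average;
centred differences (np.gradient) make the extremum unique at a symmetric
step, so detection is exact at zero noise and invariant to per-cell
intensity scaling and axis translation. Channels are normalised to
reference windows relative to the boundary — *Xist* to (−4, −2) px (the
cloud-side peak), IF channels to (15, 35) px (the nucleoplasm plateau) —
and cells not covering their reference window are dropped with a log
entry. Averages report mean and interquartile band per position, keeping
positions covered by ≥ 25% of cells (a coverage rule chosen here; the
source is silent). Within-cloud enrichment is the mean normalised IF
intensity over (−10, 0) px; group comparisons use the rank-sum test.

## The synthetic-data generator

`simgen` emulates the study design: five time points {0, 4, 8, 12, 24} h,
biological duplicates, per-feature LL.4 truth for d-score decay
(b ~ U(1, 3), c ~ U(0.05, 0.30), d ~ U(0.40, 0.60), e ~ logU(2, 20)) or
B6-count gain, escapees at constant p = 0.5, XO-contaminated samples, and
clones with incomplete induction (defaults 46.64 / 59.44 / 50.61 / 48.24%
for four clones, the measured cloud fractions of the validation design).
Totals are negative-binomial — mean 500 with 60% of reads
allele-assignable (~300 allelic reads/feature/sample; depths per feature
are not published, so this is a package choice) and dispersion 0.02,
i.e. a biological CV of ~14%, typical of duplicates of an isogenic cell
line — and the allelic subset is a binomial draw of p = LL.4(t). A
noiseless mode emits real-valued expected counts so estimator-correctness
tests are exact and separate from sampling noise. One seeded generator
stream per call makes outputs byte-identical given (config, seed).

What the generator does *not* model: read-level artefacts (mappability,
GC, fragment length), SNP density variation along features,
autocorrelated noise between time points, and cell-state heterogeneity
beyond the escapee/induction mechanisms. Passing recovery tests therefore
demonstrates estimator correctness under the stated count model, not
robustness to those real-data effects.

## Problem sizes and numerical defaults

Recovery checks run at 200 features × 10 samples (~2,000 fits including
multi-start, a few seconds); grid oracles use 10,000 points; the
contamination grid uses 99 values of p; profile checks use 100 cells or
100 draws. Tolerances: closed-form-vs-grid agreement 0.01 h; noiseless
parameter recovery 1e-3; exact algebraic identities 1e-9–1e-12; sampled
recovery thresholds are stated per test (median IC35 error < 1 h, median
ED50 error < 1.5 h at ~500 allelic reads/sample).

## Known limitations

- OLS standard errors for the induction regression are valid under
  homoskedastic noise only; count-level precision weighting is out of
  scope.
- The residual statistic behind the fixed 0.2 cutoff and the per-sample
  reading of the minimum-allelic-reads filter are assumptions, both
  configurable.
- ED50 as the e parameter differs slightly from the linear-axis
  maximum-slope time for asymmetric-on-linear-scale curves.
- Kinetic statistics are point estimates; no confidence intervals are
  propagated from the fits.
- The BAM-to-count step is out of scope: counts are consumed as tables.
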