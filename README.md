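# xcikin

Allele-specific chromatin kinetics of X-chromosome inactivation (XCI).

When *Xist* is induced in a hybrid (Cast × B6) female cell line, the B6 X
chromosome is silenced: active histone marks (H3K27ac, H4ac, H3K9ac,
H3K4me3, H3K4me1) and transcription are lost from the B6 allele while
Polycomb marks (H3K27me3, H2AK119Ub) accumulate on it. With allele-resolved
ChIP-seq or RNA-seq counts over a doxycycline time course, those dynamics
can be measured per peak, per gene or per 10-kb window. `xcikin` implements
that analysis end to end for people working on XCI or any allele-specific
chromatin time course:

- **d-scores** — the allelic ratio d = reads<sup>B6</sup> /
  (reads<sup>B6</sup> + reads<sup>Cast</sup>); 0.5 is biallelic, → 0 as the
  B6 allele is silenced. Minimum-allelic-read, biallelic-at-t0 and
  replicate-stability filters; normalisation so every retained feature
  starts at 0.5.
- **Kinetics** — per-feature least-squares fits of the four-parameter
  log-logistic curve f(t) = c + (d − c) / (1 + exp(b(ln t − ln e))), and the
  derived statistics: **IC35** (time the normalised d-score crosses 0.35,
  i.e. half of the 0.5 → 0.2 dynamic range, by closed-form inversion),
  **ED50** (the half-way time e), and the **onset time** (extremum of the
  analytic second derivative on (0, ED50)), all censored at the 24-h
  horizon.
- **Accumulation** — repressive-mark gain as TMM-normalised B6 counts
  relative to t = 0, with input-outlier window masking.
- **Corrections** — the XO-contamination adjustment
  d′ = d / (d + nf − nf·d) with nf the input B6 odds p/(1 − p), and the
  induction-corrected logFC regression ~ 0 + clones + clones:induction
  that extrapolates a dox/no-dox fold change to a fully induced
  population.
- **Classification** — early/intermediate/late silencing classes
  (3-cluster k-means on IC35), sensitive/intermediate/resistant classes for
  mutant-vs-WT comparisons, and rank-sum association of the classes with
  genomic features (distance to *Xist*, entry-site proximity, LINE/gene
  density, expression) under Benjamini–Hochberg correction.
- **Genomic feature universe** — consensus peaks across replicates, active
  genes (TSS in both H3K9ac and H3K4me3 consensus peaks), promoters
  (TSS ± 2 kb), gene bodies minus the first 2 kb, enhancers
  (H3K27ac ∩ H3K4me1, ≥ 1 kb from a TSS), genome-wide and intergenic 10-kb
  windows.
- **IF/RNA-FISH profiles** — *Xist*-cloud boundary detection (minimum
  slope), boundary alignment, reference-window normalisation, profile
  averaging and within-cloud enrichment.
- **Synthetic data** — `xcikin.simgen` generates allelic count time
  courses, accumulation counts, induction mixtures and fluorescence
  profiles with known ground truth (negative-binomial totals, binomial
  allelic sampling, escapees, XO contamination, incomplete induction), so
  every estimator can be validated against truth.

Fit/transform-shaped steps follow scikit-learn conventions
(`LL4Regressor`, `TMMNormalizer`, `OrderedKMeans1D`,
`InductionEffectEstimator`); module-level functions wrap them.

## Worked example

```python
import xcikin as xk

cfg = xk.SimConfig(n_features=50, total_count_mean=500,
                   allelic_fraction_of_total=1.0, escapee_fraction=0.1, seed=7)
counts, truth = xk.simulate_timecourse(cfg)

series = xk.compute_dscores(counts, min_allelic_reads=50)
series = xk.filter_biallelic(series)           # keep d(0) in [0.3, 0.7]
series = xk.normalize_dscores(series)          # every feature starts at 0.5

keep = series.min_reads_pass & series.biallelic_pass & series.norm_defined
summary = xk.summarize_kinetics(series[keep])
print(summary[["feature_id", "ic35", "ed50", "onset", "ic35_censored"]].head())

labels = xk.kinetic_clusters(summary["ic35"].to_numpy(), k=3, seed=0)
```

prints

```
  feature_id       ic35       ed50      onset  ic35_censored
0  feat_0000   3.525715   3.931926   1.950061          False
1  feat_0001  11.766957  11.268230   6.757020          False
2  feat_0002   7.608108   9.229681   3.785039          False
3  feat_0003   7.941800  17.439830  17.439824          False
4  feat_0004   7.844328   9.842168   0.001005          False
```

Each row is one ChIP peak: `ic35` is the fitted time (hours) at which its
normalised d-score crosses 0.35 — how long the B6 allele takes to lose half
its dynamic range of the mark; `ed50` is the half-way time of the sigmoid;
`onset` is when the curve starts to move (second-derivative extremum; it
lands on an interval endpoint when the curvature is monotone over
(0, ED50)). Censored statistics are set to 24 h and flagged. On this run
the three k-means classes split 19 early / 20 intermediate / 11 late, the
five simulated escapees are all censored at 24 h, and comparing to the
generator truth gives a median |IC35 error| of 0.71 h over 42 uncensored
features.

The same pipeline is scriptable from a shell (`xcikin simgen timecourse`,
`xcikin dscore`, `xcikin kinetics`, `xcikin classify-kinetics`,
`xcikin xo`, `xcikin induction`, `xcikin profiles`); every subcommand is a
thin wrapper over the functions above.

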