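# hippotraj

Cross-sectional trajectory analysis of hippocampal and subfield volumes
across age, sex and APOE genotype — the statistical pipeline used to ask
whether, and when, carriers of the strongest common genetic risk factor
for Alzheimer's disease (homozygous APOE ε4) diverge from non-carriers
in healthy ageing.

The package is for biostatisticians and imaging researchers working with
participant-level tables of imaging-derived phenotypes (regional volumes
in mm³, one row per subject).  Because population imaging cohorts are
access-restricted, it ships a synthetic cohort generator that emulates
the relevant statistical structure (ages 44–82, skewed genotype
frequencies, linear volume decline with a post-65 change point that is
strongest in female e4/e4 carriers), so every stage is testable without
any data download.

## Methods at a glance

* **Preprocessing** — clinical exclusions; per-region outlier screening
  with the unscaled median absolute deviation
  (flag `i` iff |xᵢ − med(x)| / MAD(x) > 5, MAD = med|x − med(x)|);
  OLS residualization of scanner confounds (scan date, table position,
  head-size scaling); log volume ratios
  log(v_region / (v_GM − v_hippocampus)).
* **Sliding-window curves** — a model-free conditional mean: a rank
  window holding 10% of subjects moves along the sorted age axis
  (100 centers, evenly spaced in quantile space); window means are
  smoothed with a Gaussian kernel of SD 20 percentile points.  No
  functional form for the age trajectory is assumed.
* **Window-wise permutation tests** — for two genotype strata, matched
  windows are compared with a two-sample t whose null is built by
  shuffling group labels within the window;
  p = (1 + #{|t*| ≥ |t|}) / (B + 1), Benjamini–Hochberg FDR across
  windows.
* **Bootstrap KS age matching** — window-wise comparison assumes the
  strata have matching age distributions; a bespoke bootstrap calibrates
  the two-sample Kolmogorov–Smirnov D (null width per group =
  (P99 − P1)/2 of D against own resamples; cutoff = max of group
  null means plus width; matched iff the 99% CI of the cross-group D
  contains the cutoff).
* **Factorial ANOVA** — Type III, sum-to-zero coding:
  APOE (4 levels) × age group (<65 / ≥65) × sex.
* **Annualized slopes** — per region, OLS models
  (i) `v ~ age`, (ii) `v ~ age * sex`, (iii) `v ~ age * APOE`,
  each coefficient normalized to percent of mean volume per year.

## Worked example

```python
import hippotraj as ht

table = ht.generate_cohort(ht.CohortSpec(n_subjects=20000, seed=7))
clean, report = ht.preprocess_pipeline(table)

curves, _ = ht.stratified_curves(clean, "whole_hippocampus", "apoe",
                                 ht.WindowSpec(n_windows=25))
res = ht.window_permutation_test(curves["e3/e3"], curves["e4/e4"],
                                 n_permutations=20000, alpha=0.001, seed=2)
```

The smoothed whole-hippocampus curves (mm³ against window mean age)
print as:

```
   age     e3/e3     e4/e4      gap
  51.3      7735      7720       15
  57.7      7704      7696        8
  64.1      7608      7554       53
  67.0      7541      7418      123
  70.3      7471      7278      194
  76.3      7410      7164      246
```

Both genotypes decline with age, but the e3/e3 − e4/e4 gap is flat
(~sampling noise) before the mid-60s and widens steeply afterwards —
the change-point divergence the pipeline is built to detect.  The
permutation test localizes it: FDR-significant windows (P < 0.001)
appear only at mean ages above ~70, none below and none in control
temporal-lobe regions.  The slope models summarize the same effect
linearly, e.g. for the whole hippocampus at this seed an age gradient
of −0.30 %/year and an extra −0.23 %/year (SE 0.05) in e4/e4 carriers
relative to e3/e3.

The `examples/` directory has one short script per capability
(generation, preprocessing, curves, inference, ANOVA + slopes, full
pipeline); each prints the numbers it computes and what they mean.
`ht.run_pipeline(config, outdir)` executes every stage and writes a
results bundle (curves/tests/ksmatch/anova JSON, slopes CSV, manifest
with config hash and output checksums) that reproduces byte-for-byte
under a fixed seed; `ht.render_figures(outdir)` draws trajectory panels
with SEM ribbons and significance bars, and the slope bar panel.

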