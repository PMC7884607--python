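# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic cohort does and does not emulate.

## Synthetic cohort model

One row per subject: age, sex, APOE genotype (`e3/e3`, `e3/e4`,
`e4/e4`, `neither`), a clinical exclusion flag, three scanner confounds
and one bilateral volume (mm³) per registered region (whole
hippocampus, 13 FreeSurfer-style subfields, total grey matter, six
temporal-lobe control regions).

**Age** is truncated normal on [44, 82] years with untruncated mean
64.0 and SD 7.5, matching the study population's per-group summaries
(means 63.5–64.3, SDs 7.3–7.6); the truncated draw has mean ≈63.8 and
SD ≈7.2.  The distribution shape is configurable — only the moments and
support are constrained by the emulated cohort.

**Genotype** frequencies default to 0.678 / 0.265 / 0.025 / 0.032,
proportional to the emulated cohort's group sizes; e4/e4 rarity (2.5%)
is the binding constraint on downstream power and is kept faithful
rather than convenient.  Sex is Bernoulli(0.5); the clinical flag is
Bernoulli(0.05).

**Volumes** follow a piecewise-linear trajectory per region:

    v = baseline + β·(age − 44) + sex_offset·[male]
        + (δ_shared + δ_{sex,apoe})·hinge(age − 65)
        + Σ_c γ_c·baseline·confound_c + ε,   ε ~ N(0, σ²)

with `hinge(u) = max(0, u)` (a logistic hinge of configurable width is
available where a smooth change point is wanted).  Defaults, as
fractions of each region's baseline per year: hippocampal linear slope
−0.20%, total grey matter −0.35%, controls −0.30%; post-65 shared
hippocampal decline −0.25%; extra e4/e4 decline −0.8%/y (female) and
−0.4%/y (male).  The e4/e4 defaults were set analytically so that the
model-(iii) age×e4/e4 contrast lands near −0.25 %/year (the hinge
projects onto a linear age slope with coefficient
cov(hinge, age)/var(age) ≈ 0.43 under the default age law), i.e. in the
0.2–0.3 %/year range the pipeline is designed to resolve.  Noise
defaults to σ = 7.5% of baseline, a realistic coefficient of variation
for automated subfield volumetry.  Baseline volumes are plausible
healthy-adult magnitudes (e.g. whole hippocampus 7 800 mm³, CA1 head
1 000 mm³, total grey matter 620 000 mm³); per-subfield population
summaries of the emulated cohort are not public, so baselines are
representative, not calibrated.

**Confounds** (normalized scan date, table position, head-size scaling
factor) are generated independent of age so residualization can be
validated in isolation; effects are expressed as a fraction of baseline
per unit confound so a single setting is meaningful across regions
spanning four orders of magnitude.  Optional multiplicative
contamination (`outlier_prob`, `outlier_scale`) emulates gross
segmentation failures for the outlier-screening stage.

What the generator does **not** emulate: spatial covariance among
subfields (volumes are conditionally independent given age/sex/
genotype), non-Gaussian volume noise, age-dependent heteroscedasticity,
genotype-dependent sampling (ages are drawn identically in every
group), and any image-level artefact.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under
the stated structure — not that real segmentations meet that structure.

## Preprocessing

Order is fixed: exclusions → per-region MAD screening → confound
residualization → (optional) log ratios.

* The MAD is deliberately **unscaled** (no 1.4826 normal-consistency
  factor) with cutoff 5, taken literally from the emulated protocol;
  the cutoff is a parameter.  A zero MAD (majority ties) makes the
  statistic degenerate: nothing is flagged and a warning is emitted.
  Flagged values are set missing for that region only — screening is
  per imaging-derived phenotype, not per subject.
* Residualization fits each region on its complete rows (intercept +
  confounds), replaces the column with residual + original mean (so
  volumes stay in mm³; downstream statistics are invariant to the
  re-centering), and drops rank-deficient confound columns with a
  warning.  It is idempotent to ~1e-10 and leaves |r| < 1e-10 with
  every confound.  Fitting is pooled across sexes (configurable).
* "Rest of grey matter" = total grey matter minus bilateral whole
  hippocampus; the `total_gm` denominator is available.  Non-positive
  numerators/denominators drop the row with a warning.

## Sliding-window curves

Windows are rank-based: window k is the contiguous run of
`round(0.10·N)` age-sorted subjects centered at quantile q_k, with
centers evenly spaced from occupancy/2 to 1 − occupancy/2 (default 100
centers).  End windows are shifted inward, keeping occupancy constant —
so the extreme windows cover a wider age span, which is the intended
behaviour when data thin out at the age extremes.  Ties in age break by
stable input order, making results deterministic and membership
invariant under any order-preserving transform of age.

Smoothing is a Gaussian kernel average of the raw window means in
quantile space, SD = 0.20 (the conventional "width 20%" is read as the
SD in percentile units; an FWHM reading and an age-space smoothing mode
are flags).  The kernel is truncated and renormalized at the
boundaries — no padding or reflection — which keeps every smoothed
value a convex combination of raw means.  SEM is computed on raw
window members, the conservative choice, and is what the figure
ribbons show.

## Window-wise permutation inference

Matched windows (same quantile center; curves must share a WindowSpec)
are compared with a pooled-variance two-sample t (Welch optional).
"At least as extreme" is two-sided by default.  The p-value uses the
add-one estimator (1 + b)/(B + 1), which never returns 0 and keeps the
test valid; FDR correction is Benjamini–Hochberg across the windows of
one comparison (per region), matching per-panel significance bars.
Windows with fewer than two members in either group are skipped and
reported.

Implementation: a label shuffle only determines which pool members land
in group a, and for the pooled t the within-group sum of squares is
T2 − n₁m₁² − n₂m₂², so the permuted statistic is a function of the
subset sums S and S2 alone.  Uniform random subsets of the smaller
group side are drawn with Floyd's algorithm vectorized across
permutations (O(B·k) per window rather than O(B·n) full shuffles),
in chunks to bound memory.  The permutation p for a small window was
checked against exhaustive enumeration of all label assignments.

**Permutation resolution.** The smallest attainable raw p is
1/(B + 1), so with m windows and k windows at that floor the smallest
attainable BH-adjusted p is m/(k(B+1)).  To display FDR significance at
P < 0.001 over 100 windows when an effect occupies only ~10 windows,
B must be ≳ 20 000; the pipeline defaults to B = 20 000 for
significance-bar displays at that threshold and documents B as a
parameter everywhere.

## Bootstrap KS age matching

At population sample sizes the plain two-sample KS test rejects
trivially small age-distribution differences, so significance is
calibrated by resampling: each group's null D distribution comes from
comparing the group with 1 000–5 000 of its own bootstrap resamples;
its width is (P99 − P1)/2; the cutoff is the maximum over groups of
(null mean + width).  The cross distribution pools D(original a,
resample of b) with D(original b, resample of a); its (P1, P99)
interval is the 99% CI for the between-group D, and the groups are
*matched* iff the CI contains the cutoff.  The procedure is symmetric
in the two groups.  It needs ≥50 subjects per group and ≥100 resamples
(percentile stability); the bootstrap D values are computed by an
index-count batch routine verified against `scipy.stats.ks_2samp`
value-for-value, including ties.

## Factorial ANOVA and annualized slopes

The ANOVA uses Type III sums of squares with sum-to-zero contrasts
(the convention of the point-and-click statistics package the emulated
protocol used), APOE × age group (<65 / ≥65) × sex, and refuses designs
with empty cells.  Effects whose sum of squares is at rounding-noise
level report F = 0.  η² = SS_effect / SS_total is included.

Slope models are fitted per region:

* (i) `v ~ age`;
* (ii) `v ~ age * sex` (reference female);
* (iii) `v ~ age * APOE` (reference e3/e3, "neither" excluded by
  default).

The `*` is Wilkinson notation: models (ii)/(iii) contain the group main
effect and the age×group interaction.  An interaction-only variant
(`include_main_effects=False`) exists for comparison but is strongly
attenuated for late-life deficits: without a group intercept a hinge-
shaped deficit projects almost entirely onto the shared terms, shrinking
the interaction by an order of magnitude, so the full model is the
default and the choice is recorded in the output rows.  Normalization
divides by the analysis population's mean volume (a reference-group
mean is optional); normalized slopes are in percent per year and are
invariant to rescaling all volumes.  Slopes are computed on
residualized volumes by default; "annualized" is a cross-sectional
between-subject gradient, not a longitudinal atrophy rate.

## Reproducibility

All randomness flows from one root seed: `numpy.random.SeedSequence`
children are spawned per stage (cohort, permutation tests per region,
KS match) in a fixed order, so stages re-run independently yet
reproducibly and a full pipeline run is byte-identical under a fixed
seed.  The manifest records the config hash, derived seeds, per-stage
row counts and SHA-256 checksums of every output.

## Problem sizes

Desk-scale defaults used by the test-suite and the acceptance script:
cohorts of 20 000 subjects (50 000 for distributional checks), 100
windows at 10% occupancy, 1 000–20 000 permutations per window, 1 000–
2 000 bootstrap resamples, 200 replicate runs for calibration checks.
These sizes give the error-rate and recovery checks 3-SE resolution
while a full run stays in the tens of seconds on one CPU.

## Known limitations

* The e4/e4 stratum is small by construction (2.5%); window-wise tests
  against it have modest power, and per-window SEM ribbons are wide —
  faithful to the emulated cohort, but worth remembering when reading
  "no significant difference" in young windows.
* The KS matching rule is a heuristic calibration, not a formal test:
  its "99% confidence" refers to bootstrap percentiles, and the
  matched/not-matched verdict should be read as a design check for the
  window pairing, not as evidence about distributional equality.
* MAD screening at cutoff 5 can clip genuine extreme-age deficits if
  measurement noise is much smaller than the planted effects; with the
  default noise level this bias is negligible, but it is a real
  interaction between screening and effect size.
* Type III tests with unbalanced, strongly skewed genotype cells are
  conservative for the smallest cells; cell sizes are reported in the
  result object.
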