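"""Model-free sliding-window trajectories, stratified by genotype.

Each window holds 10% of a stratum's subjects, moved along the sorted
age axis; window means are smoothed with a Gaussian kernel (SD = 20
percentile points) in quantile space.  No linearity assumption is made,
so the post-65 acceleration shows up directly in the curve.
"""

import numpy as np

import hippotraj as ht

table = ht.generate_cohort(ht.CohortSpec(n_subjects=20000, seed=7))
clean, _ = ht.preprocess_pipeline(table)

spec = ht.WindowSpec(occupancy=0.10, n_windows=25, kernel_width=0.20)
curves, skipped = ht.stratified_curves(clean, "whole_hippocampus", "apoe", spec)
print("strata:", ", ".join(f"{k} (n={c.n_subjects})" for k, c in curves.items()))
if skipped:
    print("skipped (too small):", skipped)

print("\nwhole-hippocampus smoothed mean volume (mm^3) by window mean age:")
print(f"{'age':>6}  {'e3/e3':>8}  {'e4/e4':>8}  {'gap':>7}")
a, b = curves["e3/e3"], curves["e4/e4"]
for i in range(0, 25, 4):
    gap = a.smoothed_mean[i] - b.smoothed_mean[i]
    print(f"{a.mean_age[i]:6.1f}  {a.smoothed_mean[i]:8.0f}  "
          f"{b.smoothed_mean[i]:8.0f}  {gap:7.0f}")

print("\nThe e3/e3 - e4/e4 gap widens in the windows past age ~65,")
print("the change-point decline planted for e4/e4 carriers.")
print("per-window SEM (e4/e4, first window):",
      np.round(b.sem[0], 1), "mm^3 - small strata give wide ribbons.")
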