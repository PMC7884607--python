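"""Factorial ANOVA and annualized percent volume change.

The ANOVA (Type III, sum-to-zero coding) tests APOE group x age group
(<65 / >=65) x sex on hippocampal and total grey-matter volume.  The
slope models quantify the cross-sectional age gradient per region as a
percent of mean volume per year, with age-by-sex and age-by-APOE
interaction contrasts.
"""

import hippotraj as ht

table = ht.generate_cohort(ht.CohortSpec(n_subjects=20000, seed=7))
clean, _ = ht.preprocess_pipeline(table)

for dep in ("whole_hippocampus", "total_grey_matter"):
    res = ht.factorial_anova(clean, dep)
    print(f"\nANOVA on {dep} (n={res.n}):")
    print(res.effects[["F", "p", "eta_sq"]].round(4).to_string())

panel = ht.slope_panel(clean, ["whole_hippocampus", "CA1_head", "HATA"])
show = panel[panel["term"].str.startswith("age")]
print("\nannualized percent volume change (% / year):")
print(show[["region", "model", "term", "normalized_slope", "normalized_se", "p"]]
      .round(4).to_string(index=False))
print("\n'age' rows: the common cross-sectional decline (~-0.3 %/y);")
print("'age:e4/e4': the extra annual loss in e4/e4 carriers relative to")
print("e3/e3 - the generator plants a post-65 decline, which this linear")
print("contrast summarizes as roughly -0.2 to -0.3 %/y.")
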