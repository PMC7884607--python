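"""Annualized cross-sectional percent volume change per region.

Three reduced linear models quantify the age gradient of volume and how
it differs by sex and APOE genotype:

    (i)   volume ~ age
    (ii)  volume ~ age * sex
    (iii) volume ~ age * APOE

In Wilkinson notation the ``*`` in (ii) and (iii) expands to the group
main effect plus the age-by-group interaction; without the main effect
a late-life group deficit projects almost entirely onto the shared
intercept and the interaction is attenuated by an order of magnitude,
so the main effect is included by default
(``include_main_effects=False`` gives the interaction-only fit).  Each
coefficient (mm^3 per year) is normalized to percent per year by
dividing by a reference volume, by default the sample mean volume of the
analysis population.  "Annualized" is a cross-sectional age gradient
between subjects, not a longitudinal atrophy rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols

from .regions import validate_region

__all__ = ["annualized_percent_change", "slope_panel", "MODELS"]

MODELS = ("age", "age_sex", "age_apoe")

_DEFAULT_REFERENCE = {"sex": "female", "apoe": "e3/e3"}


def _model_formula(model: str, reference: dict[str, str],
                   main_effects: bool) -> str:
    if model == "age":
        return "y ~ age"
    factor = {"age_sex": "sex", "age_apoe": "apoe"}.get(model)
    if factor is None:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    coded = f"C({factor}, Treatment('{reference[factor]}'))"
    if main_effects:
        return f"y ~ age * {coded}"
    return f"y ~ age + age:{coded}"


def _term_label(raw: str) -> str:
    # age:C(sex, Treatment('female'))[T.male] -> age:male
    # C(sex, Treatment('female'))[T.male]     -> male
    if "[T." not in raw:
        return raw
    level = raw.split("[T.")[1].rstrip("]")
    return f"age:{level}" if raw.startswith("age:") else level


def annualized_percent_change(
    table: pd.DataFrame,
    region: str,
    model: str = "age",
    reference_levels: dict[str, str] | None = None,
    normalization: str = "sample_mean",
    include_neither: bool = False,
    include_main_effects: bool = True,
) -> pd.DataFrame:
    """Fit one reduced model for one region; return its slope rows.

    Returns a DataFrame with one row per model term (the age slope and,
    for models (ii)/(iii), each interaction contrast against the
    reference level), with the raw coefficient, its standard error and
    p-value, and the normalized slope in percent of the reference volume
    per year.  For model (iii) the contrasts compare e3/e4 and e4/e4
    carriers against e3/e3; the "neither" group is excluded unless
    ``include_neither`` is set.

    ``normalization``: "sample_mean" (default) divides by the analysis
    population's mean volume; "reference_mean" by the reference group's
    mean volume.
    """
    validate_region(region)
    reference = {**_DEFAULT_REFERENCE, **(reference_levels or {})}
    if normalization not in ("sample_mean", "reference_mean"):
        raise ValueError("normalization must be 'sample_mean' or 'reference_mean'")

    cols = ["age", region] + (["sex"] if model == "age_sex" else []) + (
        ["apoe"] if model == "age_apoe" else []
    )
    df = table[cols].rename(columns={region: "y"}).dropna()
    if model == "age_apoe" and not include_neither:
        df = df[df["apoe"] != "neither"]

    factor = {"age_sex": "sex", "age_apoe": "apoe"}.get(model)
    if factor is not None:
        sizes = df[factor].value_counts()
        if reference[factor] not in sizes.index:
            raise ValueError(f"empty reference level {reference[factor]!r}")
        if (sizes == 0).any() or len(sizes) < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 non-empty levels")
        if (sizes < 30).any():
            small = sizes[sizes < 30].to_dict()
            warnings.warn(
                f"levels with fewer than 30 subjects: {small}; "
                "slope estimates will be unstable",
                RuntimeWarning,
            )

    fit = ols(_model_formula(model, reference, include_main_effects), data=df).fit()
    if normalization == "sample_mean":
        norm = float(df["y"].mean())
    else:
        ref_rows = df if factor is None else df[df[factor] == reference[factor]]
        norm = float(ref_rows["y"].mean())
    if norm <= 0:
        raise ValueError("non-positive normalization volume")

    rows = []
    for raw_name in fit.params.index:
        if raw_name == "Intercept":
            continue
        coef = float(fit.params[raw_name])
        se = float(fit.bse[raw_name])
        rows.append(
            {
                "region": region,
                "model": model,
                "term": _term_label(raw_name),
                "coef": coef,
                "se": se,
                "p": float(fit.pvalues[raw_name]),
                "normalized_slope": 100.0 * coef / norm,
                "normalized_se": 100.0 * se / norm,
                "norm_volume": norm,
                "n": int(fit.nobs),
                "main_effects": include_main_effects,
            }
        )
    return pd.DataFrame(rows)


def slope_panel(
    table: pd.DataFrame,
    regions,
    models=MODELS,
    reference_levels: dict[str, str] | None = None,
    normalization: str = "sample_mean",
) -> pd.DataFrame:
    """Slope rows for every region x model combination."""
    frames = [
        annualized_percent_change(
            table, region, model,
            reference_levels=reference_levels,
            normalization=normalization,
        )
        for region in regions
        for model in models
    ]
    return pd.concat(frames, ignore_index=True)
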