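"""Exclusion, robust outlier screening, confound regression and
ratio normalization for participant volume tables.

Pipeline order is fixed: clinical exclusions -> per-region MAD outlier
removal -> confound residualization -> (optionally) log volume ratios.
Outlier removal is per imaging-derived phenotype: a flagged value is set
missing for that region only, the subject's other regions are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import ALL_REGIONS, CONFOUND_COLUMNS, WHOLE_HIPPOCAMPUS, TOTAL_GREY_MATTER

__all__ = [
    "PreprocessReport",
    "apply_exclusions",
    "mad_outliers",
    "remove_outliers",
    "residualize_confounds",
    "volume_ratio",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    """Row-count bookkeeping for one preprocessing run."""

    n_input: int = 0
    n_excluded_clinical: int = 0
    n_outliers_removed: dict[str, int] = field(default_factory=dict)
    confound_r2: dict[str, float] = field(default_factory=dict)
    n_output: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_clinical": self.n_excluded_clinical,
            "n_outliers_removed": dict(self.n_outliers_removed),
            "confound_r2": dict(self.confound_r2),
            "n_output": self.n_output,
        }


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop subjects with a neurological/psychiatric exclusion flag."""
    if "excluded_flag" not in table.columns:
        raise ValueError("table has no 'excluded_flag' column")
    flagged = table["excluded_flag"].astype(bool)
    kept = table.loc[~flagged].reset_index(drop=True)
    report = PreprocessReport(
        n_input=len(table),
        n_excluded_clinical=int(flagged.sum()),
        n_output=len(kept),
    )
    return kept, report


def mad_outliers(values, cutoff: float = 5.0) -> np.ndarray:
    """Flag values whose deviation from the median exceeds ``cutoff`` MADs.

    The MAD is left unscaled (median of absolute deviations, no normal
    consistency factor): ``outlier[i] = |x[i] - med| / MAD > cutoff``.
    Missing values are never flagged.  A zero MAD (majority ties) makes
    the statistic degenerate; nothing is flagged and a warning is
    emitted.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values for MAD screening")
    med = np.median(x[finite])
    abs_dev = np.abs(x - med)
    mad = np.median(abs_dev[finite])
    if mad == 0:
        warnings.warn(
            "MAD is zero (tied values); no outliers flagged", RuntimeWarning
        )
        return np.zeros(x.shape, dtype=bool)
    mask = np.zeros(x.shape, dtype=bool)
    mask[finite] = abs_dev[finite] / mad > cutoff
    return mask


def remove_outliers(
    table: pd.DataFrame,
    regions=ALL_REGIONS,
    cutoff: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Set MAD-flagged volumes missing, independently per region."""
    out = table.copy()
    counts: dict[str, int] = {}
    for region in regions:
        mask = mad_outliers(out[region].to_numpy(dtype=float), cutoff=cutoff)
        counts[region] = int(mask.sum())
        if mask.any():
            out.loc[mask, region] = np.nan
    return out, counts


def _design_matrix(table: pd.DataFrame, confounds) -> tuple[np.ndarray, list[str]]:
    """Intercept + confound columns, dropping collinear columns."""
    cols = list(confounds)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in cols])
    # drop confounds that add no rank (constant or collinear)
    keep: list[int] = [0]
    kept_names: list[str] = []
    for j, name in enumerate(cols, start=1):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
            kept_names.append(name)
        else:
            warnings.warn(
                f"confound {name!r} is collinear/constant and was dropped",
                RuntimeWarning,
            )
    return X[:, keep], kept_names


def residualize_confounds(
    table: pd.DataFrame,
    confounds=CONFOUND_COLUMNS,
    regions=ALL_REGIONS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Regress confounds out of every volume column.

    Each volume column is replaced by its OLS residual against the
    confounds (with intercept) plus the original column mean, so volumes
    stay on an interpretable mm^3 scale.  Missing volumes stay missing;
    each region is fitted on its own complete rows.  Returns the table
    and the per-region confound R^2.
    """
    missing = [c for c in confounds if c not in table.columns]
    if missing:
        raise ValueError(f"confound columns absent from table: {missing}")
    if len(table) <= len(confounds) + 1:
        raise ValueError("need more rows than confounds + 1 to residualize")
    out = table.copy()
    X_full, kept = _design_matrix(table, confounds)
    r2: dict[str, float] = {}
    for region in regions:
        y = out[region].to_numpy(dtype=float)
        ok = np.isfinite(y)
        X = X_full[ok]
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        fitted = X @ beta
        resid = y[ok] - fitted
        tss = np.sum((y[ok] - y[ok].mean()) ** 2)
        r2[region] = float(1.0 - np.sum(resid**2) / tss) if tss > 0 else 0.0
        new = np.full_like(y, np.nan)
        new[ok] = resid + y[ok].mean()
        out[region] = new
    return out, r2


def volume_ratio(
    table: pd.DataFrame,
    region: str,
    denominator_mode: str = "rest_of_gm",
) -> pd.Series:
    """Natural-log ratio of a regional volume to a grey-matter denominator.

    ``rest_of_gm`` divides by total grey matter minus the bilateral whole
    hippocampus (the region is compared against grey matter outside the
    hippocampal formation); ``total_gm`` divides by total grey matter.
    Rows with a non-positive numerator or denominator are dropped with a
    warning.
    """
    if denominator_mode not in ("rest_of_gm", "total_gm"):
        raise ValueError("denominator_mode must be 'rest_of_gm' or 'total_gm'")
    num = table[region].astype(float)
    gm = table[TOTAL_GREY_MATTER].astype(float)
    if denominator_mode == "rest_of_gm":
        denom = gm - table[WHOLE_HIPPOCAMPUS].astype(float)
    else:
        denom = gm
    valid = (num > 0) & (denom > 0) & num.notna() & denom.notna()
    if not valid.all():
        warnings.warn(
            f"volume_ratio({region}): dropped {int((~valid).sum())} rows with "
            "missing or non-positive volumes",
            RuntimeWarning,
        )
    return np.log(num[valid] / denom[valid])


def preprocess_pipeline(
    table: pd.DataFrame,
    mad_cutoff: float = 5.0,
    confounds=CONFOUND_COLUMNS,
    regions=ALL_REGIONS,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Exclusions -> per-region MAD outliers -> confound residualization."""
    kept, report = apply_exclusions(table)
    kept, counts = remove_outliers(kept, regions=regions, cutoff=mad_cutoff)
    report.n_outliers_removed = counts
    kept, r2 = residualize_confounds(kept, confounds=confounds, regions=regions)
    report.confound_r2 = r2
    report.n_output = len(kept)
    return kept, report
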