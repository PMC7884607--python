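"""Inference on sliding-window curves and factorial group comparisons.

Three procedures:

* per-window two-sample permutation t-tests between two strata's
  curves, with Benjamini-Hochberg FDR correction across windows;
* a bootstrap calibration of the two-sample Kolmogorov-Smirnov statistic
  that decides whether two age distributions are matched closely enough
  for window-wise comparison to be meaningful (large cohorts make the
  plain KS test reject trivial differences);
* Type III factorial ANOVA (sum-to-zero contrasts) of volume on APOE
  group x age group (<65 / >=65) x sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .windows import WindowCurve

__all__ = [
    "WindowTestResult",
    "KSMatchResult",
    "AnovaResult",
    "window_permutation_test",
    "bh_fdr",
    "ks_match",
    "factorial_anova",
]


# ---------------------------------------------------------------------------
# per-window permutation t-tests


@dataclass
class WindowTestResult:
    """Per-window permutation test between two group curves."""

    center_quantile: np.ndarray
    mean_age: np.ndarray          # average of the two groups' window mean ages
    t_observed: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    skipped_windows: list[int]
    group_a: str = ""
    group_b: str = ""
    region: str = ""
    n_permutations: int = 0
    alpha: float = 0.001
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "seed": self.seed,
            "center_quantile": self.center_quantile.tolist(),
            "mean_age": self.mean_age.tolist(),
            "t_observed": self.t_observed.tolist(),
            "p_raw": self.p_raw.tolist(),
            "p_fdr": self.p_fdr.tolist(),
            "significant": self.significant.astype(bool).tolist(),
            "skipped_windows": list(self.skipped_windows),
        }


def _t_stat(xa: np.ndarray, xb: np.ndarray, variant: str) -> float:
    """Two-sample t; rows of 2-D inputs are treated as replicates."""
    na, nb = xa.shape[-1], xb.shape[-1]
    ma, mb = xa.mean(axis=-1), xb.mean(axis=-1)
    va, vb = xa.var(axis=-1, ddof=1), xb.var(axis=-1, ddof=1)
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:  # welch
        denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def _extreme_count(pool: np.ndarray, na: int, t_obs: float, B: int,
                   rng: np.random.Generator, variant: str,
                   alternative: str, chunk: int = 4096) -> int:
    """Count label shuffles whose t is at least as extreme as ``t_obs``.

    A shuffle only determines which pool members fall in group a, so the
    permuted t is a function of the subset sums: with T = sum(pool),
    T2 = sum(pool^2), S and S2 the subset sums,
    (n1-1)v1 + (n2-1)v2 = T2 - n1 m1^2 - n2 m2^2.  Uniform random
    subsets (of the smaller group side, whose size is k) are drawn with
    Floyd's algorithm vectorized across permutations — O(B k) work per
    window instead of O(B n) full shuffles — in chunks to bound memory.
    """
    n = len(pool)
    nb = n - na
    swap = na > nb            # sample the smaller side; flips the t sign
    k = nb if swap else na
    n2 = n - k
    T = float(pool.sum())
    T2 = float(np.sum(pool**2))
    count = 0
    done = 0
    while done < B:
        b = min(chunk, B - done)
        taken = np.zeros((b, n), dtype=bool)
        S = np.zeros(b)
        S2 = np.zeros(b)
        rows = np.arange(b)
        for j in range(n - k, n):
            t_idx = rng.integers(0, j + 1, size=b)
            chosen = np.where(taken[rows, t_idx], j, t_idx)
            taken[rows, chosen] = True
            vals = pool[chosen]
            S += vals
            S2 += vals * vals
        m1 = S / k
        m2 = (T - S) / n2
        v1 = np.maximum(S2 - k * m1**2, 0.0) / (k - 1)
        v2 = np.maximum(T2 - S2 - n2 * m2**2, 0.0) / (n2 - 1)
        if variant == "pooled":
            sp2 = ((k - 1) * v1 + (n2 - 1) * v2) / (n - 2)
            denom = np.sqrt(sp2 * (1.0 / k + 1.0 / n2))
        else:
            denom = np.sqrt(v1 / k + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / denom
        t = np.where(denom == 0, 0.0, t)
        if swap:
            t = -t
        if alternative == "two-sided":
            count += int((np.abs(t) >= abs(t_obs)).sum())
        else:
            count += int((t >= t_obs).sum())
        done += b
    return count


def window_permutation_test(
    curve_a: WindowCurve,
    curve_b: WindowCurve,
    n_permutations: int = 5000,
    alpha: float = 0.001,
    seed: int = 0,
    alternative: str = "two-sided",
    t_variant: str = "pooled",
) -> WindowTestResult:
    """Permutation t-tests between matched windows of two curves.

    Windows pair by center quantile (the curves must share a WindowSpec).
    Within each matched window, group labels are shuffled
    ``n_permutations`` times and ``p = (1 + #extreme) / (B + 1)`` — the
    add-one estimator keeps p off zero and the test exact.  "Extreme"
    means ``|t| >= |t_obs|`` two-sided (default) or ``t >= t_obs``
    one-sided ("greater").  FDR is Benjamini-Hochberg across this
    comparison's windows; a window with fewer than two members in either
    group is skipped and reported.
    """
    if curve_a.spec != curve_b.spec:
        raise ValueError("curves were built with different WindowSpecs")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    if t_variant not in ("pooled", "welch"):
        raise ValueError("t_variant must be 'pooled' or 'welch'")
    rng = np.random.default_rng(seed)
    k = len(curve_a.center_quantile)
    t_obs = np.full(k, np.nan)
    p_raw = np.full(k, np.nan)
    skipped: list[int] = []
    B = int(n_permutations)
    for i in range(k):
        xa = np.asarray(curve_a.member_values[i], dtype=float)
        xb = np.asarray(curve_b.member_values[i], dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            skipped.append(i)
            continue
        t_obs[i] = _t_stat(xa, xb, t_variant)
        pool = np.concatenate([xa, xb])
        extreme = _extreme_count(
            pool, len(xa), float(t_obs[i]), B, rng, t_variant, alternative
        )
        p_raw[i] = (1.0 + extreme) / (B + 1.0)

    tested = np.isfinite(p_raw)
    p_fdr = np.full(k, np.nan)
    if tested.any():
        p_fdr[tested] = bh_fdr(p_raw[tested])
    significant = np.zeros(k, dtype=bool)
    significant[tested] = p_fdr[tested] < alpha
    return WindowTestResult(
        center_quantile=curve_a.center_quantile.copy(),
        mean_age=(curve_a.mean_age + curve_b.mean_age) / 2.0,
        t_observed=t_obs,
        p_raw=p_raw,
        p_fdr=p_fdr,
        significant=significant,
        skipped_windows=skipped,
        group_a=curve_a.stratum,
        group_b=curve_b.stratum,
        region=curve_a.region,
        n_permutations=B,
        alpha=alpha,
        seed=seed,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# bootstrap KS age-distribution matching


@dataclass
class KSMatchResult:
    """Bootstrap-calibrated KS comparison of two age distributions."""

    d_observed: float
    null_mean: dict[str, float]
    null_width: dict[str, float]   # (P99 - P1)/2 of each group's bootstrap null
    cutoff: float
    ci99: tuple[float, float]      # (P1, P99) of the cross D distribution
    matched: bool
    n_boot: int = 0
    seed: int = 0
    labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return {
            "d_observed": self.d_observed,
            "null_mean": dict(self.null_mean),
            "null_width": dict(self.null_width),
            "cutoff": self.cutoff,
            "ci99": list(self.ci99),
            "matched": bool(self.matched),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "labels": list(self.labels),
        }


def _resample_ks(ref_sorted: np.ndarray, src_sorted: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
    """KS D between ``ref_sorted`` and each bootstrap resample of
    ``src_sorted`` encoded as an index matrix ``idx`` (rows of draws
    into ``src_sorted``).

    Because a resample only takes values of the source sample, its ECDF
    jumps only at source values; evaluating both right-continuous ECDFs
    at the union of ref and source values is exact (ties included) and
    equals ``scipy.stats.ks_2samp`` row by row, without materializing
    the resampled vectors.
    """
    B, m = idx.shape
    offsets = (np.arange(B) * m)[:, None]
    counts = np.bincount((idx + offsets).ravel(), minlength=B * m).reshape(B, m)
    cum = np.cumsum(counts, axis=1) / m   # resample ECDF at src_sorted[j]
    pts = np.concatenate([ref_sorted, src_sorted])
    f_ref = np.searchsorted(ref_sorted, pts, side="right") / len(ref_sorted)
    pos = np.searchsorted(src_sorted, pts, side="right") - 1
    f_res = cum[:, np.clip(pos, 0, m - 1)]
    f_res[:, pos < 0] = 0.0
    return np.abs(f_res - f_ref).max(axis=1)


def ks_match(
    age_a,
    age_b,
    n_boot: int = 5000,
    seed: int = 0,
    labels: tuple[str, str] = ("a", "b"),
) -> KSMatchResult:
    """Decide whether two age distributions are statistically matched.

    For each group, ``n_boot`` same-size bootstrap resamples are drawn
    and the KS D between the group and each of its own resamples
    approximates that group's null D distribution.  Each null
    distribution's width is half its P99-P1 range, and the significance
    cutoff is ``max_g(mean_g + width_g)``.  The cross distribution pools
    D(original a, resample of b) with D(original b, resample of a); its
    (P1, P99) interval is the 99% CI for the between-group D.  The
    groups are *matched* iff that CI contains the cutoff — i.e. the
    between-group D is not distinguishable from pure resampling
    variability at 99% confidence.
    """
    a = np.sort(np.asarray(age_a, dtype=float))
    b = np.sort(np.asarray(age_b, dtype=float))
    if len(a) < 50 or len(b) < 50:
        raise ValueError("ks_match needs at least 50 values per group")
    if n_boot < 100:
        raise ValueError("n_boot below 100 makes the percentile estimates unstable")
    rng = np.random.default_rng(seed)
    d_obs = float(stats.ks_2samp(a, b).statistic)

    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    null_a = _resample_ks(a, a, idx_a)
    null_b = _resample_ks(b, b, idx_b)
    width = {
        labels[0]: float((np.percentile(null_a, 99) - np.percentile(null_a, 1)) / 2),
        labels[1]: float((np.percentile(null_b, 99) - np.percentile(null_b, 1)) / 2),
    }
    mean = {labels[0]: float(null_a.mean()), labels[1]: float(null_b.mean())}
    cutoff = max(mean[g] + width[g] for g in labels)

    cross = np.concatenate([_resample_ks(a, b, idx_b), _resample_ks(b, a, idx_a)])
    ci99 = (float(np.percentile(cross, 1)), float(np.percentile(cross, 99)))
    matched = ci99[0] <= cutoff <= ci99[1]
    return KSMatchResult(
        d_observed=d_obs,
        null_mean=mean,
        null_width=width,
        cutoff=float(cutoff),
        ci99=ci99,
        matched=matched,
        n_boot=n_boot,
        seed=seed,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# factorial ANOVA


@dataclass
class AnovaResult:
    """Type III factorial ANOVA summary."""

    dependent: str
    effects: pd.DataFrame  # index: effect; columns: sum_sq, df, F, p, eta_sq
    factor_levels: dict[str, list] = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "n": self.n,
            "factor_levels": {k: list(v) for k, v in self.factor_levels.items()},
            "effects": {
                str(ix): {c: float(v) for c, v in row.items()}
                for ix, row in self.effects.iterrows()
            },
        }


def factorial_anova(
    table: pd.DataFrame,
    dependent: str,
    factors: tuple[str, ...] = ("apoe", "age_group", "sex"),
    age_split: float = 65.0,
) -> AnovaResult:
    """Full factorial ANOVA of a volume on APOE x age group x sex.

    Uses Type III sums of squares with sum-to-zero factor coding.  If an
    ``age_group`` factor is requested but absent, it is derived from
    ``age`` as ``<split`` / ``>=split`` (default 65).  Every cell of the
    factorial design must be non-empty.
    """
    df = table.copy()
    if "age_group" in factors and "age_group" not in df.columns:
        df["age_group"] = np.where(
            df["age"] < age_split, f"<{age_split:g}", f">={age_split:g}"
        )
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor column {f!r} absent from table")
    if dependent not in df.columns:
        raise ValueError(f"dependent column {dependent!r} absent from table")
    df = df.dropna(subset=[dependent, *factors])

    levels = {f: sorted(df[f].astype(str).unique()) for f in factors}
    cell_counts = (
        df.groupby([df[f].astype(str) for f in factors], observed=False)
        .size()
        .reindex(
            pd.MultiIndex.from_product(levels.values(), names=factors),
            fill_value=0,
        )
    )
    empty = [tuple(ix) for ix, c in cell_counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty design cells: {empty}")

    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = ols(f"Q('{dependent}') ~ {terms}", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = anova_lm(model, typ=3)
    aov = aov.drop(index="Intercept")
    ss_total = float(aov["sum_sq"].sum())
    resid_df = float(aov.loc["Residual", "df"])
    eff = aov.drop(index="Residual").copy()
    # sums of squares at rounding-noise level (zero-variance effects)
    # produce meaningless F ratios; report them as exactly null
    tiny = 1e-18 * max(float(np.sum(df[dependent] ** 2)), 1.0)
    degenerate = eff["sum_sq"].to_numpy() <= tiny
    eff["F"] = np.where(degenerate, 0.0, eff["F"].to_numpy())
    eff["PR(>F)"] = np.where(degenerate, 1.0, eff["PR(>F)"].to_numpy())
    eff["PR(>F)"] = eff["PR(>F)"].fillna(1.0)
    eff["eta_sq"] = eff["sum_sq"] / ss_total if ss_total > tiny else 0.0
    eff = eff.rename(columns={"PR(>F)": "p"})
    eff["df_resid"] = resid_df
    eff.index = [
        ix.replace("C(", "").replace(", Sum)", "") for ix in eff.index
    ]
    return AnovaResult(
        dependent=dependent,
        effects=eff[["sum_sq", "df", "df_resid", "F", "p", "eta_sq"]],
        factor_levels=levels,
        n=len(df),
    )
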