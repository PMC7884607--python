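"""Model-free sliding-window conditional mean curves.

A fixed-occupancy age-quantile window is moved along the sorted age
axis: each window holds the same *number* of subjects (a fixed fraction
of the sample), so windows in the dense middle of the age distribution
span few years while the extreme windows span a wider age range.  Raw
per-window means are smoothed with a Gaussian kernel in quantile space.
No functional form is assumed for the age trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WindowSpec", "WindowCurve", "sliding_window_curve", "stratified_curves"]


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the sliding window.

    occupancy
        Fraction of the sample inside each window (default 0.10).
    n_windows
        Number of window centers, evenly spaced in quantile space from
        occupancy/2 to 1 - occupancy/2 (default 100, percentile
        resolution).
    kernel_width
        Gaussian smoothing kernel SD, in quantile units (default 0.20).
        With ``kernel_interp="fwhm"`` the value is taken as a full width
        at half maximum instead.
    smooth_space
        "quantile" (default) smooths over window-center quantiles;
        "age" smooths over window mean ages with the kernel width
        interpreted as a fraction of the observed age span.
    """

    occupancy: float = 0.10
    n_windows: int = 100
    kernel_width: float = 0.20
    kernel_interp: str = "sd"
    smooth_space: str = "quantile"

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.kernel_interp not in ("sd", "fwhm"):
            raise ValueError("kernel_interp must be 'sd' or 'fwhm'")
        if self.smooth_space not in ("quantile", "age"):
            raise ValueError("smooth_space must be 'quantile' or 'age'")

    @property
    def kernel_sd(self) -> float:
        if self.kernel_interp == "fwhm":
            return self.kernel_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.kernel_width


@dataclass
class WindowCurve:
    """Per-window summaries of one measure in one stratum.

    ``members`` holds, per window, the positions (into the original
    input vectors, after pairwise-finite filtering) of the subjects in
    that window; ``member_values`` the corresponding y values — kept so
    window-wise permutation tests can re-use the exact memberships.
    """

    center_quantile: np.ndarray
    mean_age: np.ndarray
    raw_mean: np.ndarray
    smoothed_mean: np.ndarray
    sem: np.ndarray
    n_in_window: np.ndarray
    members: list = field(repr=False, default_factory=list)
    member_values: list = field(repr=False, default_factory=list)
    spec: WindowSpec = field(default_factory=WindowSpec)
    region: str = ""
    stratum: str = ""
    n_subjects: int = 0

    def to_dict(self) -> dict:
        """JSON-serializable summary (memberships omitted)."""
        return {
            "region": self.region,
            "stratum": self.stratum,
            "n_subjects": self.n_subjects,
            "spec": {
                "occupancy": self.spec.occupancy,
                "n_windows": self.spec.n_windows,
                "kernel_width": self.spec.kernel_width,
                "kernel_interp": self.spec.kernel_interp,
                "smooth_space": self.spec.smooth_space,
            },
            "center_quantile": self.center_quantile.tolist(),
            "mean_age": self.mean_age.tolist(),
            "raw_mean": self.raw_mean.tolist(),
            "smoothed_mean": self.smoothed_mean.tolist(),
            "sem": self.sem.tolist(),
            "n_in_window": self.n_in_window.tolist(),
        }


def window_bounds(n: int, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank ranges [start, stop) of each window for a sample of size n.

    Window k is the contiguous run of ``round(occupancy * n)`` age ranks
    centered at quantile ``q_k``, truncated (shifted inward) at the two
    ends so every window keeps the same occupancy.
    """
    w = int(round(spec.occupancy * n))
    w = max(1, min(n, w))
    if spec.n_windows == 1:
        centers = np.array([0.5])
    else:
        centers = np.linspace(spec.occupancy / 2, 1 - spec.occupancy / 2, spec.n_windows)
    start = np.rint(centers * n - w / 2).astype(int)
    start = np.clip(start, 0, n - w)
    return centers, start, start + w


def sliding_window_curve(age, y, spec: WindowSpec = WindowSpec(), *,
                         region: str = "", stratum: str = "") -> WindowCurve:
    """Conditional mean curve of ``y`` against ``age``.

    Pairs with a missing value in either vector are dropped.  Subjects
    are sorted by age with ties broken by stable input order, so results
    are deterministic and window membership depends on age only through
    ranks (any order-preserving transform of age leaves membership
    unchanged).
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.shape != y.shape:
        raise ValueError("age and y must have equal length")
    ok = np.isfinite(age) & np.isfinite(y)
    age, y = age[ok], y[ok]
    n = len(age)
    w = int(round(spec.occupancy * n))
    if n == 0 or n < max(1, w) or w < 1:
        raise ValueError(
            f"sample of {n} too small for occupancy {spec.occupancy}"
        )
    if np.ptp(age) == 0 and n > 1:
        raise ValueError("age vector has zero variance")

    order = np.argsort(age, kind="stable")
    age_s, y_s = age[order], y[order]
    orig_pos = np.flatnonzero(ok)[order]

    centers, starts, stops = window_bounds(n, spec)
    k = len(centers)
    mean_age = np.empty(k)
    raw = np.empty(k)
    sem = np.empty(k)
    counts = np.empty(k, dtype=int)
    members: list[np.ndarray] = []
    values: list[np.ndarray] = []
    for i, (a, b) in enumerate(zip(starts, stops)):
        seg = y_s[a:b]
        mean_age[i] = age_s[a:b].mean()
        raw[i] = seg.mean()
        sem[i] = seg.std(ddof=1) / np.sqrt(len(seg)) if len(seg) > 1 else 0.0
        counts[i] = len(seg)
        members.append(orig_pos[a:b].copy())
        values.append(seg.copy())

    smoothed = _gaussian_smooth(centers, mean_age, raw, spec)
    return WindowCurve(
        center_quantile=centers,
        mean_age=mean_age,
        raw_mean=raw,
        smoothed_mean=smoothed,
        sem=sem,
        n_in_window=counts,
        members=members,
        member_values=values,
        spec=spec,
        region=region,
        stratum=stratum,
        n_subjects=n,
    )


def _gaussian_smooth(centers: np.ndarray, mean_age: np.ndarray,
                     raw: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Kernel-weighted average of raw window means.

    Weights are renormalized at the boundary (truncated kernel, no
    padding), so every smoothed value is a convex combination of raw
    means and lies inside their range.
    """
    if spec.smooth_space == "quantile":
        x = centers
        sd = spec.kernel_sd
    else:
        x = mean_age
        span = np.ptp(mean_age)
        sd = spec.kernel_sd * (span if span > 0 else 1.0)
    d = (x[:, None] - x[None, :]) / sd
    wts = np.exp(-0.5 * d**2)
    wts /= wts.sum(axis=1, keepdims=True)
    return wts @ raw


def stratified_curves(
    table: pd.DataFrame,
    values,
    by,
    spec: WindowSpec = WindowSpec(),
    *,
    region: str = "",
) -> tuple[dict[str, WindowCurve], list[str]]:
    """One curve per stratum of the grouping columns in ``by``.

    ``values`` is a column name or a Series aligned with ``table``
    (e.g. a log-ratio from :func:`~hippotraj.preprocess.volume_ratio`).
    Strata too small for the window spec are skipped and listed in the
    second return value.
    """
    by = [by] if isinstance(by, str) else list(by)
    if not by:
        raise ValueError("need at least one grouping column")
    if isinstance(values, str):
        region = region or values
        values = table[values]
    values = pd.Series(np.asarray(values, dtype=float), index=values.index) \
        if isinstance(values, pd.Series) else pd.Series(values, index=table.index)

    curves: dict[str, WindowCurve] = {}
    skipped: list[str] = []
    for key, grp in table.groupby(by, sort=True, observed=True):
        label = "/".join(key) if isinstance(key, tuple) else str(key)
        yv = values.reindex(grp.index)
        try:
            curves[label] = sliding_window_curve(
                grp["age"].to_numpy(), yv.to_numpy(), spec,
                region=region, stratum=label,
            )
        except ValueError:
            skipped.append(label)
    if not curves and not skipped:
        raise ValueError("no strata found")
    return curves, skipped
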