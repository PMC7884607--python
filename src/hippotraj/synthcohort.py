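"""Synthetic participant cohorts with the statistical structure of a
population imaging study of hippocampal ageing.

The generator emulates a cross-sectional cohort aged 44-82 (truncated
normal, mean 64.0, SD 7.5), sex-balanced, with APOE genotype frequencies
heavily skewed toward e3/e3 and e4/e4 rare.  Every regional volume
declines linearly with age; hippocampal regions additionally carry a
piecewise-linear change-point decline after age 65 that is strongest in
female e4/e4 carriers.  Scanner confounds (scan date, table position,
head-size scaling) act linearly on volumes and are generated independent
of age by default so that confound residualization can be tested in
isolation.

Volumes are bilateral mm^3.  Nothing here simulates images or
segmentation: regional volumes are drawn directly from the trajectory
model, which is what the downstream statistics consume.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .regions import (
    ALL_REGIONS,
    APOE_LEVELS,
    CONFOUND_COLUMNS,
    CONTROL_REGIONS,
    HIPPOCAMPAL_REGIONS,
    META_COLUMNS,
    SEX_LEVELS,
    TOTAL_GREY_MATTER,
)

__all__ = [
    "CohortSpec",
    "TrajectorySpec",
    "default_trajectories",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "load_cohort_config",
]

#: default genotype frequencies (e3/e3, e3/e4, e4/e4, neither),
#: proportional to group sizes 19519 / 7625 / 724 / 959
DEFAULT_GENOTYPE_PROBS: dict[str, float] = {
    "e3/e3": 0.678,
    "e3/e4": 0.265,
    "e4/e4": 0.025,
    "neither": 0.032,
}

#: default per-confound linear effects, as a fraction of the region
#: baseline per unit of the (standardized) confound
DEFAULT_CONFOUND_EFFECTS: dict[str, float] = {
    "scan_date": 0.005,
    "table_position": 0.002,
    "head_size": 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling design of a synthetic cohort.

    ``noise_sd`` is the SD of additive Gaussian volume noise expressed as
    a fraction of each region's baseline (``noise_mode="fraction"``,
    default) or as an absolute mm^3 value applied to every region
    (``noise_mode="absolute"``).  ``outlier_prob``/``outlier_scale``
    contaminate individual volume entries multiplicatively, emulating
    gross segmentation failures.
    """

    n_subjects: int
    seed: int = 0
    age_low: float = 44.0
    age_high: float = 82.0
    age_mean: float = 64.0
    age_sd: float = 7.5
    genotype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROBS)
    )
    sex_prob_female: float = 0.5
    exclusion_prob: float = 0.05
    confound_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_EFFECTS)
    )
    noise_sd: float = 0.075
    noise_mode: str = "fraction"
    outlier_prob: float = 0.0
    outlier_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be strictly below age_high")
        if set(self.genotype_probs) != set(APOE_LEVELS):
            raise ValueError(f"genotype_probs must have keys {APOE_LEVELS}")
        total = math.fsum(self.genotype_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype_probs sum to {total}, expected 1")
        for name, p in [
            ("sex_prob_female", self.sex_prob_female),
            ("exclusion_prob", self.exclusion_prob),
            ("outlier_prob", self.outlier_prob),
            *((f"genotype_probs[{g}]", p) for g, p in self.genotype_probs.items()),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.noise_mode not in ("fraction", "absolute"):
            raise ValueError("noise_mode must be 'fraction' or 'absolute'")
        if unknown := set(self.confound_effects) - set(CONFOUND_COLUMNS):
            raise ValueError(f"unknown confounds: {sorted(unknown)}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-linear mean volume trajectory for one region.

    mean(age, sex, apoe) = baseline_volume
                           + linear_slope * (age - age_low)
                           + sex_offset * [sex == male]
                           + (shared + group extra slope) * hinge(age)

    where ``hinge(age) = max(0, age - changepoint_age)`` for the default
    piecewise hinge, or ``(age - c) * expit((age - c)/logistic_width)``
    for the smooth variant.  ``post_changepoint_extra_slope`` maps
    (sex, apoe) pairs to additional mm^3/year after the change point;
    ``post_changepoint_shared_slope`` applies to every subject.
    """

    region: str
    baseline_volume: float
    linear_slope: float
    sex_offset: float = 0.0
    changepoint_age: float = 65.0
    post_changepoint_shared_slope: float = 0.0
    post_changepoint_extra_slope: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    hinge: str = "piecewise"
    logistic_width: float = 3.0

    def __post_init__(self) -> None:
        if self.region not in ALL_REGIONS:
            raise KeyError(f"unknown region {self.region!r}")
        if self.baseline_volume <= 0:
            raise ValueError("baseline_volume must be positive")
        if self.hinge not in ("piecewise", "logistic"):
            raise ValueError("hinge must be 'piecewise' or 'logistic'")
        for sex, apoe in self.post_changepoint_extra_slope:
            if sex not in SEX_LEVELS or apoe not in APOE_LEVELS:
                raise KeyError(f"unknown (sex, apoe) group {(sex, apoe)!r}")

    def hinge_values(self, age: np.ndarray) -> np.ndarray:
        d = np.asarray(age, dtype=float) - self.changepoint_age
        if self.hinge == "piecewise":
            return np.maximum(0.0, d)
        from scipy.special import expit

        return d * expit(d / self.logistic_width)

    def mean_volume(self, age: np.ndarray, sex: np.ndarray, apoe: np.ndarray,
                    age_low: float) -> np.ndarray:
        """Noise- and confound-free mean volume for each subject."""
        age = np.asarray(age, dtype=float)
        extra = np.full(age.shape, self.post_changepoint_shared_slope)
        for (s, g), slope in self.post_changepoint_extra_slope.items():
            extra = extra + slope * ((np.asarray(sex) == s) & (np.asarray(apoe) == g))
        return (
            self.baseline_volume
            + self.linear_slope * (age - age_low)
            + self.sex_offset * (np.asarray(sex) == "male")
            + extra * self.hinge_values(age)
        )


# Plausible bilateral baselines (mm^3 at age 44) for a FreeSurfer-style
# parcellation; the study cohort's per-subfield summaries are not public,
# so these are representative healthy-adult magnitudes.
_BASELINES: dict[str, float] = {
    "whole_hippocampus": 7800.0,
    "parasubiculum": 130.0,
    "presubiculum_head": 260.0,
    "presubiculum_body": 320.0,
    "subiculum_head": 340.0,
    "subiculum_body": 490.0,
    "CA1_head": 1000.0,
    "CA1_body": 330.0,
    "CA3_head": 240.0,
    "CA3_body": 180.0,
    "CA4": 500.0,
    "GC_ML_DG": 560.0,
    "molecular_layer": 1100.0,
    "HATA": 120.0,
    "total_grey_matter": 620000.0,
    "superior_temporal": 22000.0,
    "middle_temporal": 24000.0,
    "inferior_temporal": 20000.0,
    "fusiform": 17000.0,
    "parahippocampal": 8000.0,
    "temporal_pole": 15000.0,
}

# Default fractional slopes (per year, as a fraction of baseline):
# a slow pre-65 hippocampal decline against a faster global grey-matter
# decline, with an extra post-65 hippocampal decline in all groups that
# is strongest in e4/e4 carriers, especially women.
_LINEAR_FRAC = {"hippocampal": -0.002, "gm": -0.0035, "control": -0.003}
_POST65_SHARED_FRAC = -0.0025
_POST65_EXTRA_FRAC = {("female", "e4/e4"): -0.008, ("male", "e4/e4"): -0.004}
_SEX_OFFSET_FRAC = 0.035


def default_trajectories(changepoint: bool = True) -> dict[str, TrajectorySpec]:
    """One TrajectorySpec per registered region, with the default effects.

    With ``changepoint=False`` every post-change-point slope is zero and
    volumes are globally linear in age.
    """
    out: dict[str, TrajectorySpec] = {}
    for region in ALL_REGIONS:
        base = _BASELINES[region]
        if region == TOTAL_GREY_MATTER:
            frac = _LINEAR_FRAC["gm"]
        elif region in CONTROL_REGIONS:
            frac = _LINEAR_FRAC["control"]
        else:
            frac = _LINEAR_FRAC["hippocampal"]
        hippocampal = region in HIPPOCAMPAL_REGIONS
        out[region] = TrajectorySpec(
            region=region,
            baseline_volume=base,
            linear_slope=frac * base,
            sex_offset=_SEX_OFFSET_FRAC * base,
            post_changepoint_shared_slope=(
                _POST65_SHARED_FRAC * base if changepoint and hippocampal else 0.0
            ),
            post_changepoint_extra_slope=(
                {g: s * base for g, s in _POST65_EXTRA_FRAC.items()}
                if changepoint and hippocampal
                else {}
            ),
        )
    return out


def _truncated_normal_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    a = (spec.age_low - spec.age_mean) / spec.age_sd
    b = (spec.age_high - spec.age_mean) / spec.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd,
        size=spec.n_subjects, random_state=rng,
    )


def generate_cohort(
    spec: CohortSpec,
    trajectories: Mapping[str, TrajectorySpec] | None = None,
) -> pd.DataFrame:
    """Draw a participant table of ``spec.n_subjects`` rows.

    ``trajectories`` must provide one :class:`TrajectorySpec` per
    registered region (defaults to :func:`default_trajectories`).  The
    draw is deterministic given ``spec.seed``: demographics, confounds,
    then per-region noise and contamination are consumed from a single
    RNG stream in a fixed order.
    """
    if trajectories is None:
        trajectories = default_trajectories()
    for region in trajectories:
        if region not in ALL_REGIONS:
            raise KeyError(f"unknown region in trajectories: {region!r}")
    missing = [r for r in ALL_REGIONS if r not in trajectories]
    if missing:
        raise ValueError(f"trajectories missing regions: {missing}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = _truncated_normal_ages(spec, rng)
    sex = np.where(rng.random(n) < spec.sex_prob_female, "female", "male")
    apoe = rng.choice(
        APOE_LEVELS, size=n, p=[spec.genotype_probs[g] for g in APOE_LEVELS]
    )
    excluded = rng.random(n) < spec.exclusion_prob
    confounds = {
        "scan_date": rng.uniform(-1.0, 1.0, n),
        "table_position": rng.standard_normal(n),
        "head_size": 0.1 * rng.standard_normal(n),
    }

    data: dict[str, object] = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "apoe": apoe,
        "excluded_flag": excluded,
        **confounds,
    }
    for region in ALL_REGIONS:
        traj = trajectories[region]
        vol = traj.mean_volume(age, sex, apoe, spec.age_low)
        conf_term = np.zeros(n)
        for cname, coef in spec.confound_effects.items():
            conf_term += coef * traj.baseline_volume * confounds[cname]
        sd = (
            spec.noise_sd * traj.baseline_volume
            if spec.noise_mode == "fraction"
            else spec.noise_sd
        )
        noise = sd * rng.standard_normal(n) if sd > 0 else 0.0
        vol = vol + conf_term + noise
        if spec.outlier_prob > 0:
            contaminate = rng.random(n) < spec.outlier_prob
            vol = np.where(contaminate, vol * spec.outlier_scale, vol)
        data[region] = vol

    return pd.DataFrame(data, columns=list(META_COLUMNS) + list(ALL_REGIONS))


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a participant table as CSV with the canonical header."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    # 17 significant digits: doubles round-trip exactly through read_cohort
    table.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    """Read a participant table, validating header and volume columns.

    Round-trips :func:`write_cohort` output field-for-field (floats are
    serialized with full repr precision).
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    numeric = ["age", *CONFOUND_COLUMNS, *[r for r in ALL_REGIONS if r in table.columns]]
    for col in numeric:
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"column {col!r} is not numeric")
    table["excluded_flag"] = table["excluded_flag"].astype(bool)
    return table


def load_cohort_config(path) -> tuple[CohortSpec, dict[str, TrajectorySpec]]:
    """Build (CohortSpec, trajectories) from a YAML config.

    The ``cohort`` mapping holds CohortSpec fields; the optional
    ``trajectories`` mapping overrides per-region TrajectorySpec fields
    on top of the defaults, plus a top-level ``changepoint: false`` to
    disable change-point modelling entirely.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    spec = CohortSpec(**cfg.get("cohort", {}))
    trajs = default_trajectories(changepoint=cfg.get("changepoint", True))
    for region, overrides in (cfg.get("trajectories") or {}).items():
        if region not in trajs:
            raise KeyError(f"unknown region in config: {region!r}")
        if "post_changepoint_extra_slope" in overrides:
            overrides = dict(overrides)
            overrides["post_changepoint_extra_slope"] = {
                tuple(k.split(":")): v
                for k, v in overrides["post_changepoint_extra_slope"].items()
            }
        trajs[region] = dataclasses.replace(trajs[region], **overrides)
    return spec, trajs
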