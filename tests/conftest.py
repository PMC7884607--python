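import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hippotraj as ht
from hippotraj.regions import ALL_REGIONS

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """800-subject cohort under the default study conditions."""
    return ht.generate_cohort(ht.CohortSpec(n_subjects=800, seed=11))


@pytest.fixture(scope="session")
def clean_cohort() -> pd.DataFrame:
    """Preprocessed 6000-subject cohort (no clinical exclusions drawn)."""
    table = ht.generate_cohort(
        ht.CohortSpec(n_subjects=6000, seed=12, exclusion_prob=0.0)
    )
    clean, _ = ht.preprocess_pipeline(table)
    return clean


def flat_trajectories(baseline: float = 3000.0) -> dict:
    """All regions constant at ``baseline``: no age, sex or group effects."""
    return {
        r: ht.TrajectorySpec(region=r, baseline_volume=baseline, linear_slope=0.0)
        for r in ALL_REGIONS
    }


# ---------------------------------------------------------------------------
# independent brute-force oracles (pure Python where practical)


def brute_force_windows(age, y, occupancy, n_windows):
    """Rank-window enumeration with plain Python slicing and statistics.

    Returns (membership lists, raw means, sems) for comparison against
    the vectorized sliding-window implementation.
    """
    import statistics

    n = len(age)
    order = sorted(range(n), key=lambda i: (age[i], i))
    w = int(round(occupancy * n))
    w = max(1, min(n, w))
    if n_windows == 1:
        centers = [0.5]
    else:
        centers = list(np.linspace(occupancy / 2, 1 - occupancy / 2, n_windows))
    members, means, sems = [], [], []
    for c in centers:
        s = int(np.rint(c * n - w / 2))
        s = min(max(s, 0), n - w)
        idx = order[s : s + w]
        vals = [y[i] for i in idx]
        members.append(idx)
        means.append(statistics.fmean(vals))
        sems.append(
            statistics.stdev(vals) / len(vals) ** 0.5 if len(vals) > 1 else 0.0
        )
    return members, means, sems


def brute_force_mad_mask(values, cutoff=5.0):
    """Outlier mask via plain-Python median computations."""
    import statistics

    finite = [v for v in values if np.isfinite(v)]
    med = statistics.median(finite)
    mad = statistics.median([abs(v - med) for v in finite])
    if mad == 0:
        return [False] * len(values)
    return [
        bool(np.isfinite(v)) and abs(v - med) / mad > cutoff for v in values
    ]


def brute_force_bh(pvals):
    """Step-up Benjamini-Hochberg by explicit enumeration."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
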