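"""Permutation-test, FDR, bootstrap-KS and factorial-ANOVA contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import hippotraj as ht
from hippotraj.inference import _resample_ks

from conftest import brute_force_bh


def _two_group_curves(rng, n=400, shift=0.0, n_windows=10):
    age_a = rng.uniform(44, 82, n)
    age_b = rng.uniform(44, 82, n)
    ya = rng.standard_normal(n)
    yb = rng.standard_normal(n) + shift
    spec = ht.WindowSpec(occupancy=0.2, n_windows=n_windows)
    return (
        ht.sliding_window_curve(age_a, ya, spec),
        ht.sliding_window_curve(age_b, yb, spec),
    )


# -- permutation tests -------------------------------------------------------


def test_identical_groups_give_zero_t_and_p_one():
    rng = np.random.default_rng(0)
    curve_a, _ = _two_group_curves(rng)
    res = ht.window_permutation_test(curve_a, curve_a, n_permutations=200, seed=1)
    np.testing.assert_array_equal(res.t_observed, 0.0)
    np.testing.assert_array_equal(res.p_raw, 1.0)
    np.testing.assert_array_equal(res.p_fdr, 1.0)
    assert not res.significant.any()
    assert res.skipped_windows == []


def test_permutation_p_bounds_and_determinism():
    rng = np.random.default_rng(2)
    ca, cb = _two_group_curves(rng, shift=0.3)
    r1 = ht.window_permutation_test(ca, cb, n_permutations=300, seed=7)
    r2 = ht.window_permutation_test(ca, cb, n_permutations=300, seed=7)
    np.testing.assert_array_equal(r1.p_raw, r2.p_raw)
    assert (r1.p_raw >= 1.0 / 301.0).all()
    assert (r1.p_raw <= 1.0).all()
    assert (r1.p_fdr >= r1.p_raw - 1e-15).all()
    r3 = ht.window_permutation_test(ca, cb, n_permutations=300, seed=8)
    assert not np.array_equal(r1.p_raw, r3.p_raw)


def test_strong_shift_detected_everywhere():
    rng = np.random.default_rng(3)
    ca, cb = _two_group_curves(rng, n=600, shift=2.0)
    res = ht.window_permutation_test(ca, cb, n_permutations=2000, alpha=0.001, seed=4)
    assert res.significant.all()
    assert (res.p_raw == 1.0 / 2001.0).all()


def test_mismatched_specs_rejected():
    rng = np.random.default_rng(5)
    ca, _ = _two_group_curves(rng, n_windows=10)
    _, cb = _two_group_curves(rng, n_windows=12)
    with pytest.raises(ValueError, match="WindowSpec"):
        ht.window_permutation_test(ca, cb)


def test_undersized_windows_are_skipped_and_reported():
    spec = ht.WindowSpec(occupancy=0.5, n_windows=3)
    rng = np.random.default_rng(6)
    ca = ht.sliding_window_curve(rng.uniform(44, 82, 40), rng.standard_normal(40), spec)
    cb = ht.sliding_window_curve(np.array([50.0, 60.0]), np.array([1.0, 2.0]), spec)
    res = ht.window_permutation_test(ca, cb, n_permutations=100, seed=0)
    assert res.skipped_windows == [0, 1, 2]  # every window has n_b = 1
    assert np.isnan(res.p_raw).all()


def test_raw_pvalues_uniform_under_null():
    # pooled p-values across replicate null datasets sit on the uniform
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(40):
        ca, cb = _two_group_curves(rng, n=150, n_windows=5)
        res = ht.window_permutation_test(
            ca, cb, n_permutations=199, seed=int(rng.integers(2**31))
        )
        pvals.extend(res.p_raw.tolist())
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_permutation_p_converges_to_exact_enumeration():
    # one tiny window: the exact two-sided permutation p is the fraction
    # of the C(8,4) group-a subsets with |t| >= |t_obs|
    from itertools import combinations

    from hippotraj.inference import _t_stat

    pool = np.array([0.3, 1.9, -0.7, 2.4, 0.1, -1.2, 3.5, 0.8])
    na = 4
    t_obs = _t_stat(pool[:na], pool[na:], "pooled")
    exact = np.mean(
        [
            abs(
                _t_stat(
                    pool[list(c)],
                    pool[[i for i in range(8) if i not in c]],
                    "pooled",
                )
            )
            >= abs(t_obs) - 1e-12
            for c in combinations(range(8), na)
        ]
    )
    spec = ht.WindowSpec(occupancy=1.0, n_windows=1)
    ca = ht.sliding_window_curve([1.0, 2, 3, 4], pool[:na], spec)
    cb = ht.sliding_window_curve([1.0, 2, 3, 4], pool[na:], spec)
    B = 40_000
    res = ht.window_permutation_test(ca, cb, n_permutations=B, seed=3)
    se = np.sqrt(exact * (1 - exact) / B)
    assert abs(res.p_raw[0] - exact) < 3 * se + 2 / B, (res.p_raw[0], exact)


# -- Benjamini-Hochberg ------------------------------------------------------


def test_bh_hand_example_and_degenerate_cases():
    np.testing.assert_allclose(
        ht.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], rtol=1e-12
    )
    np.testing.assert_allclose(ht.bh_fdr([0.2]), [0.2])
    np.testing.assert_array_equal(ht.bh_fdr([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        ht.bh_fdr([])
    with pytest.raises(ValueError):
        ht.bh_fdr([0.5, 1.5])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
)
def test_bh_matches_brute_force_step_up(pvals):
    np.testing.assert_allclose(
        ht.bh_fdr(pvals), brute_force_bh(pvals), rtol=1e-12, atol=1e-15
    )


def test_bh_monotone_in_input_order():
    rng = np.random.default_rng(8)
    for _ in range(50):
        p = rng.random(rng.integers(2, 40))
        adj = ht.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


# -- bootstrap KS matching ---------------------------------------------------


def test_resample_ks_equals_scipy_on_random_instances():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n, m = rng.integers(5, 60, size=2)
        ref = np.sort(rng.choice(np.arange(20.0), n))      # heavy ties
        src = np.sort(rng.choice(np.arange(15.0), m))      # ties across samples
        idx = rng.integers(0, m, size=(4, m))
        got = _resample_ks(ref, src, idx)
        want = [stats.ks_2samp(ref, src[row]).statistic for row in idx]
        np.testing.assert_allclose(got, want, rtol=1e-12)


def test_identical_samples_have_zero_observed_d():
    a = np.repeat([1.0, 2.0, 3.0], 20)
    res = ht.ks_match(a, a.copy(), n_boot=100, seed=0)
    assert res.d_observed == 0.0


def test_ks_match_verdicts_and_symmetry():
    rng = np.random.default_rng(10)
    a = rng.uniform(44, 82, 600)
    b = rng.uniform(44, 82, 600)
    r_ab = ht.ks_match(a, b, n_boot=500, seed=1)
    r_ba = ht.ks_match(b, a, n_boot=500, seed=1)
    assert r_ab.matched and r_ba.matched
    assert r_ab.d_observed == r_ba.d_observed
    shifted = ht.ks_match(a, a + 15.0, n_boot=500, seed=2)
    shifted_sw = ht.ks_match(a + 15.0, a, n_boot=500, seed=2)
    assert not shifted.matched and not shifted_sw.matched
    assert shifted.ci99[0] > shifted.cutoff  # clearly separated


def test_ks_match_result_invariants():
    rng = np.random.default_rng(11)
    res = ht.ks_match(
        rng.uniform(44, 82, 300), rng.uniform(44, 82, 300), n_boot=200, seed=3
    )
    assert all(w >= 0 for w in res.null_width.values())
    assert res.ci99[0] <= res.ci99[1]
    assert res.matched == (res.ci99[0] <= res.cutoff <= res.ci99[1])


def test_ks_match_preconditions():
    rng = np.random.default_rng(12)
    a = rng.uniform(44, 82, 200)
    with pytest.raises(ValueError, match="50"):
        ht.ks_match(a[:10], a, n_boot=200)
    with pytest.raises(ValueError, match="n_boot"):
        ht.ks_match(a, a, n_boot=50)


# -- factorial ANOVA ---------------------------------------------------------


def _balanced_table(n_per_cell=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for apoe in ht.regions.APOE_LEVELS:
        for ag in ("<65", ">=65"):
            for sex in ("female", "male"):
                for _ in range(n_per_cell):
                    rows.append(
                        {
                            "apoe": apoe,
                            "age_group": ag,
                            "sex": sex,
                            "vol": 100.0 + noise * rng.standard_normal(),
                        }
                    )
    return pd.DataFrame(rows)


def test_anova_zero_variance_balanced_design_gives_zero_f():
    res = ht.factorial_anova(_balanced_table(), "vol")
    assert (res.effects["F"] == 0.0).all()
    assert (res.effects["eta_sq"] == 0.0).all()


def test_anova_degrees_of_freedom_match_factorial_design():
    res = ht.factorial_anova(_balanced_table(noise=1.0), "vol")
    df = res.effects["df"]
    assert df["apoe"] == 3
    assert df["age_group"] == 1
    assert df["sex"] == 1
    assert df["apoe:age_group"] == 3
    assert df["apoe:age_group:sex"] == 3
    n = 4 * 2 * 2 * 5
    assert res.effects["df_resid"].iloc[0] == n - 16


def test_anova_planted_sex_effect_dominates():
    table = _balanced_table(n_per_cell=40, noise=1.0, seed=1)
    table["vol"] += 10.0 * (table["sex"] == "male")
    res = ht.factorial_anova(table, "vol")
    f = res.effects["F"]
    assert f["sex"] > 100
    assert f["sex"] > 10 * f.drop("sex").max()
    others = res.effects.drop(index="sex")
    assert (others["p"] > 0.001).all()


def test_anova_age_split_derived_from_age(clean_cohort):
    res = ht.factorial_anova(clean_cohort, "whole_hippocampus")
    assert res.effects.loc["age_group", "p"] < 1e-6  # planted age decline
    assert set(res.factor_levels["age_group"]) == {"<65", ">=65"}
    # rows whose volume was MAD-screened out drop from the fit
    assert res.n == int(clean_cohort["whole_hippocampus"].notna().sum())


def test_anova_empty_cell_is_named():
    table = _balanced_table(noise=1.0)
    table = table[~((table["apoe"] == "e4/e4") & (table["sex"] == "male"))]
    with pytest.raises(ValueError, match="e4/e4"):
        ht.factorial_anova(table, "vol")


def test_anova_type_one_error_near_nominal():
    rng = np.random.default_rng(13)
    rejections = []
    for _ in range(60):
        table = _balanced_table(n_per_cell=12, noise=1.0, seed=int(rng.integers(2**31)))
        res = ht.factorial_anova(table, "vol")
        rejections.extend((res.effects["p"] < 0.05).tolist())
    rate = np.mean(rejections)
    n = len(rejections)
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n), rate
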