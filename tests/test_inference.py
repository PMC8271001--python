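"""Tests of correlations, paired t, and the power analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numgeo import (
    CorrelationRequest,
    PowerQuery,
    correlation_report,
    paired_t,
    partial_correlation,
    pearson,
    power_correlation,
    required_n_correlation,
)
from numgeo.errors import (
    ConfigurationError,
    DegenerateTestError,
    InsufficientDataError,
)
from numgeo.inference import partial_correlation_recursive


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------

def test_pearson_perfect_linearity():
    x = np.array([1.0, 2, 3, 4])
    res = pearson(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_pearson_hand_computed():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6])
    # manual arithmetic oracle: r = sum(dx*dy)/sqrt(sum dx^2 * sum dy^2)
    dx, dy = x - x.mean(), y - y.mean()
    r_manual = (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())
    res = pearson(x, y)
    assert res.r == pytest.approx(r_manual, abs=1e-12)
    # p from the t transform with df = n-2
    t = r_manual * np.sqrt(3) / np.sqrt(1 - r_manual**2)
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)


def test_pearson_null_case_large_n():
    rng = np.random.default_rng(0)
    res = pearson(rng.standard_normal(10_000), rng.standard_normal(10_000))
    assert abs(res.r) < 0.04


def test_pearson_pairwise_deletion_and_errors():
    x = pd.Series([1.0, 2, np.nan, 4, 5])
    y = pd.Series([2.0, np.nan, 3, 5, 7])
    res = pearson(x, y)
    assert res.n == 3
    assert res.df == 1
    with pytest.raises(InsufficientDataError):
        pearson([1.0, np.nan, 3], [np.nan, 2.0, 4])
    with pytest.raises(DegenerateTestError):
        pearson([1.0, 1, 1, 1], [1.0, 2, 3, 4])


def test_pearson_affine_invariance():
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal(50), rng.standard_normal(50)
    base = pearson(x, y).r
    assert pearson(3 * x + 2, -0.5 * y + 7).r == pytest.approx(-base, abs=1e-12)


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def test_partial_equals_recursion_formula_on_random_data():
    rng = np.random.default_rng(2)
    for _ in range(20):
        x, y, z = rng.standard_normal((3, 40))
        res = partial_correlation(x, y, [z])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        assert res.r == pytest.approx(
            partial_correlation_recursive(rxy, rxz, ryz), abs=1e-10
        )


def test_partial_reduces_to_zero_order_for_orthogonal_covariate():
    rng = np.random.default_rng(3)
    x, y = rng.standard_normal((2, 30))
    z = rng.standard_normal(30)
    # orthogonalize z against centred x and y -> sample correlations exactly 0
    design = np.column_stack([np.ones(30), x, y])
    z = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
    res = partial_correlation(x, y, [z])
    assert res.r == pytest.approx(pearson(x, y).r, abs=1e-12)


def test_partial_of_identical_series_is_one():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(25)
    z = rng.standard_normal(25)
    assert partial_correlation(x, x, [z]).r == pytest.approx(1.0, abs=1e-10)


def test_partial_multiple_covariates_matches_projection_oracle():
    rng = np.random.default_rng(5)
    x, y, z1, z2, z3 = rng.standard_normal((5, 60))
    res = partial_correlation(x, y, [z1, z2, z3])
    # brute-force projection oracle
    d = np.column_stack([np.ones(60), z1, z2, z3])
    proj = d @ np.linalg.pinv(d)
    rx, ry = x - proj @ x, y - proj @ y
    assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
    assert res.df == 60 - 2 - 3


def test_partial_against_independent_library():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.standard_normal((45, 3)), columns=["x", "y", "z"])
    res = partial_correlation(df["x"], df["y"], [df["z"]])
    ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


def test_partial_collinear_covariates_rejected():
    rng = np.random.default_rng(7)
    x, y, z = rng.standard_normal((3, 20))
    with pytest.raises(ConfigurationError, match="collinear"):
        partial_correlation(x, y, [z, 2 * z])


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_hand_computed():
    x = np.array([2.0, 4, 3, 1, 6])
    y = x - np.array([1.0, 2, 0, -1, 3])  # differences 1,2,0,-1,3
    d = x - y
    t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    t, df, p = paired_t(x, y)
    assert t == pytest.approx(t_manual, abs=1e-12)
    assert df == 4
    assert p == pytest.approx(2 * stats.t.sf(abs(t_manual), 4), rel=1e-9)


def test_paired_t_df_matches_cohort_size():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(49)
    y = x + 0.1 + rng.standard_normal(49)
    _, df, _ = paired_t(x, y)
    assert df == 48


def test_paired_t_constant_shift_degenerate():
    x = np.array([1.0, 2, 3, 4])
    with pytest.raises(DegenerateTestError):
        paired_t(x, x + 2.0)


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def test_required_n_reproduces_planning_value():
    q = PowerQuery(effect_size_r=0.34, power=0.75, alpha=0.05, tails=1)
    assert required_n_correlation(q) == 42


def test_exact_methods_agree_and_exceed_approximation():
    q = PowerQuery(effect_size_r=0.34, power=0.75, alpha=0.05, tails=1)
    n_nct = required_n_correlation(q, method="nct")
    n_exact = required_n_correlation(q, method="exact-r")
    assert n_nct == n_exact == 45


def test_power_floor_when_target_barely_above_alpha():
    q = PowerQuery(effect_size_r=0.9, power=0.051, alpha=0.05, tails=1)
    assert required_n_correlation(q) == 4


@pytest.mark.parametrize("method", ["normal-approx", "nct", "exact-r"])
def test_required_n_monotonicities(method):
    base = dict(power=0.8, alpha=0.05, tails=2)
    n_small_r = required_n_correlation(PowerQuery(effect_size_r=0.3, **base), method)
    n_large_r = required_n_correlation(PowerQuery(effect_size_r=0.5, **base), method)
    assert n_small_r >= n_large_r
    n_low_power = required_n_correlation(
        PowerQuery(effect_size_r=0.3, power=0.6, alpha=0.05, tails=2), method
    )
    assert n_low_power <= n_small_r
    n_one_tail = required_n_correlation(
        PowerQuery(effect_size_r=0.3, power=0.8, alpha=0.05, tails=1), method
    )
    assert n_one_tail <= n_small_r
    n_lax_alpha = required_n_correlation(
        PowerQuery(effect_size_r=0.3, power=0.8, alpha=0.2, tails=2), method
    )
    assert n_lax_alpha <= n_small_r


def test_exact_power_verified_by_monte_carlo():
    """The exact-method n for (r=0.5, power=0.8, two-tailed) brackets the
    target: empirical power >= 0.8 at n, < 0.8 at n-1 (1e5 replicates)."""
    q = PowerQuery(effect_size_r=0.5, power=0.8, alpha=0.05, tails=2)
    n = required_n_correlation(q, method="exact-r")

    def mc_power(n, rho=0.5, reps=100_000, seed=9):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((reps, n, 2))
        x = z[:, :, 0]
        y = rho * x + np.sqrt(1 - rho**2) * z[:, :, 1]
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        tcrit = stats.t.ppf(0.975, n - 2)
        return (np.abs(t) > tcrit).mean()

    assert mc_power(n) >= 0.8 - 0.005
    assert mc_power(n - 1) < 0.8


def test_power_query_validation():
    with pytest.raises(ConfigurationError):
        PowerQuery(effect_size_r=1.2, power=0.8)
    with pytest.raises(ConfigurationError):
        PowerQuery(effect_size_r=0.3, power=0.03, alpha=0.05)
    with pytest.raises(ConfigurationError):
        PowerQuery(effect_size_r=0.3, power=0.8, tails=3)


# ---------------------------------------------------------------------------
# correlation report
# ---------------------------------------------------------------------------

def _scores_frame(n=60, n_missing=18, seed=10):
    rng = np.random.default_rng(seed)
    age = rng.uniform(8, 11, n)
    g = 0.5 * (age - 9.5) + rng.standard_normal(n)
    f = 0.4 * g + 0.5 * (age - 9.5) + rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "child_id": [f"c{i:03d}" for i in range(n)],
            "age": age,
            "acc_overall": 0.7 + 0.05 * g,
            "acc_run1": 0.65 + 0.05 * g + 0.02 * rng.standard_normal(n),
            "acc_run2": 0.72 + 0.05 * g,
            "sensitivity": 4 + rng.standard_normal(n),
            "verbal_score": 12 + 3 * rng.standard_normal(n),
            "combined_index": f,
        }
    )
    df.loc[df.index[:n_missing], "combined_index"] = np.nan
    return df


def test_report_pairwise_ns():
    df = _scores_frame()
    report = correlation_report(df)
    battery_rows = report[(report["y"] == "combined_index")]
    assert (battery_rows["n"] == 42).all()
    other = report[(report["y"] != "combined_index") & (report["x"] != "combined_index")]
    assert (other["n"] == 60).all()


def test_report_self_correlation_flagged():
    df = _scores_frame()
    rep = correlation_report(df, [CorrelationRequest("age", "age")])
    assert rep["r"].iloc[0] == 1.0
    assert "self_correlation" in rep["flags"].iloc[0]


def test_report_unknown_variable():
    with pytest.raises(ConfigurationError, match="unknown variable"):
        correlation_report(_scores_frame(), [CorrelationRequest("age", "nope")])


def test_report_recovers_generative_correlation():
    """Zero-order r between a latent-driven measure and the outcome at
    n=500 lands within ±0.08 of an independent simulation oracle."""
    rng = np.random.default_rng(11)

    def simulate(n, rng):
        g = rng.standard_normal(n)
        f = 0.5 * g + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        acc = 0.7 + 0.1 * g + 0.05 * rng.standard_normal(n)
        z = f + 0.3 * rng.standard_normal(n)
        return acc, z

    acc, z = simulate(500, rng)
    df = pd.DataFrame({"acc_overall": acc, "combined_index": z})
    r_obs = correlation_report(df, [CorrelationRequest("acc_overall", "combined_index")])["r"].iloc[0]
    acc_o, z_o = simulate(200_000, np.random.default_rng(12))
    r_oracle = np.corrcoef(acc_o, z_o)[0, 1]
    assert r_obs == pytest.approx(r_oracle, abs=0.08)
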