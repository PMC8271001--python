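"""Tests of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from numgeo import (
    CohortConfig,
    GeometryParams,
    ProtocolConfig,
    generate_cohort,
    inject_missingness,
    sigma_from_sensitivity,
    simulate_battery,
    simulate_cohort,
    simulate_geometry_run,
    simulate_numerosity_trials,
)
from numgeo.cohort import TRAITS, geometry_success_probability
from numgeo.errors import ConfigurationError
from numgeo.psychometrics import Z75
from numgeo.scoring import get_sequence

from conftest import make_child


# ---------------------------------------------------------------------------
# Latent cohort
# ---------------------------------------------------------------------------

def test_identity_correlation_yields_independent_traits():
    cfg = CohortConfig(
        n_children=10_000,
        trait_corr=np.eye(4),
        age_slopes={t: 0.0 for t in TRAITS},
        seed=5,
    )
    children = generate_cohort(cfg)
    mat = np.array([[getattr(c, t) for t in TRAITS] for c in children])
    corr = np.corrcoef(mat.T)
    off = corr[~np.eye(4, dtype=bool)]
    assert np.all(np.abs(off) < 0.03)


def test_sample_moments_match_configuration_within_3_se():
    cfg = CohortConfig(seed=21)
    children = generate_cohort(cfg)
    n = cfg.n_children
    age_sd = (cfg.age_range[1] - cfg.age_range[0]) / np.sqrt(12)
    ages = np.array([c.age for c in children])
    assert abs(ages.mean() - cfg.mid_age) < 3 * age_sd / np.sqrt(n)
    for trait in TRAITS:
        # marginal SD includes the age-slope contribution
        marg_sd = np.hypot(cfg.trait_sds[trait], cfg.age_slopes[trait] * age_sd)
        vals = np.array([getattr(c, trait) for c in children])
        assert abs(vals.mean() - cfg.trait_means[trait]) < 3 * marg_sd / np.sqrt(n)
        assert abs(vals.std(ddof=1) - marg_sd) < 3 * marg_sd / np.sqrt(2 * (n - 1))


def test_latent_correlations_converge_at_large_n():
    corr = np.array(
        [
            [1.0, 0.2, 0.5, 0.0],
            [0.2, 1.0, 0.4, 0.3],
            [0.5, 0.4, 1.0, 0.1],
            [0.0, 0.3, 0.1, 1.0],
        ]
    )
    cfg = CohortConfig(
        n_children=5000, trait_corr=corr,
        age_slopes={t: 0.0 for t in TRAITS}, seed=9,
    )
    children = generate_cohort(cfg)
    mat = np.array([[getattr(c, t) for t in TRAITS] for c in children])
    emp = np.corrcoef(mat.T)
    mc_se = 1.0 / np.sqrt(5000)
    assert np.all(np.abs(emp - corr) < 3 * mc_se + 1e-12)


def test_same_seed_gives_identical_cohorts():
    cfg = CohortConfig(seed=3)
    a = simulate_cohort(cfg)
    b = simulate_cohort(CohortConfig(seed=3))
    for attr in ("children", "numerosity_trials", "geometry_log", "battery_items", "truth"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
    assert a.missing_battery == b.missing_battery


def test_non_psd_correlation_matrix_rejected():
    bad = np.array(
        [
            [1.0, 0.99, -0.99, 0.0],
            [0.99, 1.0, 0.99, 0.0],
            [-0.99, 0.99, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    with pytest.raises(ConfigurationError, match="positive semidefinite"):
        CohortConfig(trait_corr=bad)


def test_grades_follow_age_thresholds():
    for c in generate_cohort(CohortConfig(seed=2)):
        if c.age < 9.0:
            assert c.grade == 3
        elif c.age < 10.0:
            assert c.grade == 4
        else:
            assert c.grade == 5


# ---------------------------------------------------------------------------
# Numerosity trials
# ---------------------------------------------------------------------------

def test_trial_counts_and_probe_balance(protocol, rng):
    trials = simulate_numerosity_trials(make_child(), protocol, rng)
    assert len(trials) == 126
    probes = pd.Series([t.probe for t in trials])
    counts = probes.value_counts()
    assert sorted(counts.index) == list(range(3, 17))
    assert (counts == 9).all()
    per_session = pd.DataFrame(
        {"s": [t.session for t in trials], "p": [t.probe for t in trials]}
    ).groupby(["s", "p"]).size()
    assert (per_session == 3).all()


def test_noiseless_observer_is_a_step_function(protocol, rng):
    trials = simulate_numerosity_trials(make_child(s_num=np.inf), protocol, rng)
    for t in trials:
        if t.probe != 9:
            assert t.response_probe_greater == (t.probe > 9)


def test_indivisible_probe_range_rejected():
    with pytest.raises(ConfigurationError, match="divisible"):
        ProtocolConfig(trials_per_session=40)  # 14 probe values


def test_sigma_mapping_matches_closed_form_choice_probabilities(protocol, rng):
    """For s_num = 4.459 the observer's sigma is ln(1.2243)/z75 ~ 0.300 and
    the choice probabilities at every probe equal the hand-evaluated
    cumulative Gaussian (oracle: direct evaluation of the closed form)."""
    s = 4.459
    sigma = sigma_from_sensitivity(s)
    assert sigma == pytest.approx(np.log(1 + 1 / 4.459) / Z75, rel=1e-12)
    assert sigma == pytest.approx(0.300, abs=5e-4)
    child = make_child(s_num=s)
    trials = simulate_numerosity_trials(child, protocol, rng)
    from numgeo.cohort import response_probability

    for probe in range(3, 17):
        oracle = ndtr((np.log(probe) - np.log(9)) / sigma)
        assert response_probability(probe, 9, s) == pytest.approx(oracle, rel=1e-12)
    # empirical frequencies agree loosely with the model (9 draws per probe)
    df = pd.DataFrame({"p": [t.probe for t in trials],
                       "r": [t.response_probe_greater for t in trials]})
    emp = df.groupby("p")["r"].mean()
    model = ndtr((np.log(emp.index.to_numpy(float)) - np.log(9)) / sigma)
    assert np.all(np.abs(emp.to_numpy() - model) < 0.5)


# ---------------------------------------------------------------------------
# Geometry task
# ---------------------------------------------------------------------------

def test_geometry_ceiling_all_correct(rng):
    seq = get_sequence("repeat")
    params = GeometryParams()
    log = simulate_geometry_run(make_child(g_geo=np.inf), seq, 2, params, rng)
    assert all(ok for _, ok in log.entries)
    assert len(log.entries) == 5


def test_geometry_floor_is_chance_on_eight_positions(rng):
    seq = get_sequence("repeat")
    params = GeometryParams()
    p = geometry_success_probability(-np.inf, 1, seq.K, params)
    assert p == pytest.approx(1 / 8)
    hits = 0
    n_runs = 4000
    for _ in range(n_runs):
        log = simulate_geometry_run(make_child(g_geo=-np.inf), seq, 1, params, rng)
        hits += sum(ok for _, ok in log.entries)
    acc = hits / (3 * n_runs)
    assert acc == pytest.approx(0.125, abs=0.02)


def test_run2_boost_raises_mean_accuracy(small_cohort_data):
    from numgeo.scoring import score_all

    scores = score_all(small_cohort_data.geometry_log, None, None)
    assert scores["acc_run2"].mean() > scores["acc_run1"].mean()


def test_complexity_cost_monotone():
    params = GeometryParams()
    probs = [geometry_success_probability(0.0, 1, k, params) for k in (5, 7, 8, 10)]
    assert all(a > b for a, b in zip(probs, probs[1:]))


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def test_battery_ceiling_and_floor(protocol, rng):
    items = simulate_battery(make_child(f_formal=np.inf), protocol, rng)
    assert items["correct"].all()
    assert len(items) == 32
    # guessing floor: long-run accuracy 1/3 per item
    totals = 0
    reps = 300
    for _ in range(reps):
        items = simulate_battery(make_child(f_formal=-np.inf), protocol, rng)
        totals += items["correct"].sum()
    acc = totals / (32 * reps)
    assert acc == pytest.approx(1 / 3, abs=0.02)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def test_missingness_count_is_deterministic(small_cohort_data, rng):
    assert small_cohort_data.battery_items["child_id"].nunique() == 42


def test_missingness_rate_zero_and_one(small_cohort_data, rng):
    full = small_cohort_data.battery_items
    kept, dropped = inject_missingness(full, 0.0, rng)
    pd.testing.assert_frame_equal(kept, full)
    assert dropped == []
    kept, dropped = inject_missingness(full, 1.0, rng)
    assert kept.empty
    assert len(dropped) == full["child_id"].nunique()


def test_all_missing_battery_refuses_correlation(rng):
    from numgeo.errors import InsufficientDataError
    from numgeo.reliability import cronbach_alpha

    with pytest.raises(InsufficientDataError):
        cronbach_alpha(np.empty((0, 3)))
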