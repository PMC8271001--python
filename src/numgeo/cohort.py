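"""Synthetic cohort generator.

Simulates trial-level data for a cohort of primary-school children
performing three tasks:

* a 2AFC numerosity discrimination task (method of constant stimuli,
  probe 3..16 vs test 9, three sessions of 42 trials);
* a geometric sequence-prediction task on an octagonal grid (8 sequences,
  two runs each: 3 scored predictions in run 1, 5 in run 2);
* a 32-item three-option formal geometry battery (8 knowledge,
  24 visuo-spatial items).

Each child carries four latent traits — numerosity sensitivity (1/Weber
fraction), geometry ability, formal-geometry ability, verbal ability —
generated from a multivariate model with configurable age slopes and a
residual correlation matrix.  The generator is the ground truth for every
downstream parameter-recovery test: the 2AFC response noise is defined as

    sigma_child = ln(1 + 1/s_num) / z75,   z75 = Phi^{-1}(0.75)

so that the analysis-side JND definition (50% -> 75% spacing on the fitted
log-Gaussian curve) recovers s_num exactly in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConfigurationError
from .psychometrics import Z75, TrialRecord2AFC
from .rng import substream
from .scoring import (
    FACTORS,
    K_MIN,
    KNOWLEDGE,
    RUN1_PREDICTIONS,
    RUN2_PREDICTIONS,
    VISUOSPATIAL,
    GeometryRunLog,
    SpatialSequence,
    sequence_catalog,
)

logger = logging.getLogger(__name__)

TRAITS = ("s_num", "g_geo", "f_formal", "v_verbal")

#: protocol metadata kept for provenance only (display parameters of the
#: original stimuli); nothing is rendered.
DEFAULT_STIMULUS_METADATA: Mapping[str, str] = {
    "dot_diameter_deg": "0.2",
    "contrast": "0.90",
    "background_luminance_cd_m2": "40",
    "field_deg": "7x7",
    "eccentricity_deg": "7",
    "flash_ms": "1000",
    "isi_ms": "300",
    "patch_duration_ms": "500",
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Sizes of the three task protocols."""

    n_sessions: int = 3
    trials_per_session: int = 42
    probe_min: int = 3
    probe_max: int = 16
    test_numerosity: int = 9
    run1_predictions: int = RUN1_PREDICTIONS
    run2_predictions: int = RUN2_PREDICTIONS
    knowledge_items: int = 8
    visuospatial_items: int = 24
    options_per_item: int = 3
    stimulus_metadata: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STIMULUS_METADATA)
    )

    @property
    def probe_values(self) -> np.ndarray:
        return np.arange(self.probe_min, self.probe_max + 1)

    def __post_init__(self) -> None:
        n_probes = self.probe_max - self.probe_min + 1
        if n_probes < 2:
            raise ConfigurationError("need at least two distinct probe values")
        if self.trials_per_session % n_probes != 0:
            raise ConfigurationError(
                f"trials_per_session ({self.trials_per_session}) must be divisible "
                f"by the number of distinct probe values ({n_probes})"
            )


@dataclass(frozen=True)
class GeometryParams:
    """Response model of the sequence task.

    First-attempt success probability at each scored location:

        p = guess + (1 - guess) * logistic(baseline + ability_slope * g_geo
                                           + run2_boost * 1[run=2]
                                           - complexity_cost * (K - K_min))

    ``guess`` = 1/8 (all grid positions selectable).  The baseline default
    is calibrated so a zero-mean unit-SD latent yields run-1 accuracy near
    the observed group mean (~0.68).
    """

    ability_slope: float = 1.0
    run2_boost: float = 0.42
    complexity_cost: float = 0.25
    baseline: float = 1.31
    guess: float = 1.0 / 8.0


def default_trait_means() -> dict[str, float]:
    return {"s_num": 4.19, "g_geo": 0.0, "f_formal": 0.0, "v_verbal": 12.9}


def default_trait_sds() -> dict[str, float]:
    return {"s_num": 1.39, "g_geo": 1.0, "f_formal": 1.0, "v_verbal": 3.11}


def default_age_slopes() -> dict[str, float]:
    # per-year drifts chosen to echo the observed age correlations
    # (numerosity ~0.25, geometry ~0.57, formal geometry ~0.69; verbal
    # weighted scores are age-normed, slope 0)
    return {"s_num": 0.43, "g_geo": 0.90, "f_formal": 1.14, "v_verbal": 0.0}


def default_trait_corr() -> np.ndarray:
    # age-adjusted residual correlations among (s_num, g_geo, f_formal,
    # v_verbal); plausible values echoing the reported partial-correlation
    # pattern (numerosity-formal ~0.5, geometry-formal ~0.4, numerosity and
    # geometry nearly independent, verbal loading on geometry/formal).
    return np.array(
        [
            [1.00, 0.10, 0.50, 0.05],
            [0.10, 1.00, 0.40, 0.35],
            [0.50, 0.40, 1.00, 0.30],
            [0.05, 0.35, 0.30, 1.00],
        ]
    )


def default_battery_difficulties(protocol: ProtocolConfig | None = None) -> dict[str, np.ndarray]:
    p = protocol or ProtocolConfig()
    return {
        KNOWLEDGE: np.linspace(-1.5, 1.5, p.knowledge_items),
        VISUOSPATIAL: np.linspace(-1.5, 1.5, p.visuospatial_items),
    }


@dataclass
class CohortConfig:
    """Generative specification of a simulated cohort.

    ``trait_corr`` is the correlation matrix of the age-adjusted residual
    noise; marginal trait SDs therefore exceed ``trait_sds`` when the
    corresponding age slope is non-zero.
    """

    n_children: int = 49
    age_range: tuple[float, float] = (8.0, 10.9)
    trait_means: dict[str, float] = field(default_factory=default_trait_means)
    trait_sds: dict[str, float] = field(default_factory=default_trait_sds)
    age_slopes: dict[str, float] = field(default_factory=default_age_slopes)
    trait_corr: np.ndarray = field(default_factory=default_trait_corr)
    missing_battery_rate: float = 7.0 / 49.0
    lapse: float = 0.0
    grade_thresholds: tuple[float, float] = (9.0, 10.0)
    s_num_min: float = 0.2
    geometry: GeometryParams = field(default_factory=GeometryParams)
    battery_difficulties: dict[str, np.ndarray] | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.trait_corr, dtype=float)
        if c.shape != (len(TRAITS), len(TRAITS)):
            raise ConfigurationError(
                f"trait_corr must be {len(TRAITS)}x{len(TRAITS)}, got {c.shape}"
            )
        if not np.allclose(c, c.T):
            raise ConfigurationError("trait_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ConfigurationError("trait_corr must have a unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ConfigurationError("trait_corr is not positive semidefinite")
        if not (0.0 <= self.missing_battery_rate <= 1.0):
            raise ConfigurationError("missing_battery_rate must lie in [0, 1]")
        if not (0.0 <= self.lapse < 1.0):
            raise ConfigurationError("lapse must lie in [0, 1)")
        self.trait_corr = c

    @property
    def mid_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass(frozen=True)
class LatentChild:
    """Ground-truth traits of one simulated child."""

    child_id: str
    age: float
    grade: int
    s_num: float
    g_geo: float
    f_formal: float
    v_verbal: float


def _grade_for_age(age: float, thresholds: tuple[float, float]) -> int:
    if age < thresholds[0]:
        return 3
    if age < thresholds[1]:
        return 4
    return 5


def sigma_from_sensitivity(s_num: float) -> float:
    """Log-axis response noise implied by a normalized sensitivity.

    Inverse of the JND chain: with mu = ln(test), JND = test*(e^{z75
    sigma}-1) = test/s_num, hence sigma = ln(1 + 1/s_num)/z75.
    """
    if s_num <= 0:
        raise ConfigurationError("s_num must be positive")
    return float(np.log1p(1.0 / s_num) / Z75)


def generate_cohort(config: CohortConfig) -> list[LatentChild]:
    """Draw the latent cohort.

    trait_i = mean_i + slope_i * (age - mid age) + sd_i * eps_i with
    eps ~ N(0, trait_corr).  Deterministic for a fixed config seed.
    """
    rng = substream(config.seed, "cohort")
    n = config.n_children
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    chol = np.linalg.cholesky(
        config.trait_corr + 1e-12 * np.eye(len(TRAITS))
    )
    eps = rng.standard_normal((n, len(TRAITS))) @ chol.T
    children = []
    for i in range(n):
        vals = {}
        for j, t in enumerate(TRAITS):
            vals[t] = (
                config.trait_means[t]
                + config.age_slopes[t] * (ages[i] - config.mid_age)
                + config.trait_sds[t] * eps[i, j]
            )
        vals["s_num"] = max(vals["s_num"], config.s_num_min)
        children.append(
            LatentChild(
                child_id=f"c{i + 1:03d}",
                age=float(ages[i]),
                grade=_grade_for_age(float(ages[i]), config.grade_thresholds),
                **{k: float(v) for k, v in vals.items()},
            )
        )
    return children


# ---------------------------------------------------------------------------
# Task simulators
# ---------------------------------------------------------------------------

def response_probability(probe, test: int, s_num: float, lapse: float = 0.0):
    """P(report probe more numerous) under the log-Gaussian observer."""
    probe = np.asarray(probe, dtype=float)
    if np.isinf(s_num):
        p = np.where(probe > test, 1.0, np.where(probe < test, 0.0, 0.5))
    else:
        sigma = sigma_from_sensitivity(s_num)
        p = stats.norm.cdf(np.log(probe / test) / sigma)
    if lapse:
        p = lapse / 2 + (1 - lapse) * p
    return p


def simulate_numerosity_trials(
    child: LatentChild,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    lapse: float = 0.0,
) -> list[TrialRecord2AFC]:
    """Simulate the constant-stimuli 2AFC sessions of one child.

    Each session presents every probe value equally often in random order;
    the default protocol yields 126 trials (3 x 42) with each probe 3..16
    appearing 9 times.
    """
    values = protocol.probe_values
    repeats = protocol.trials_per_session // values.size
    trials: list[TrialRecord2AFC] = []
    for session in range(1, protocol.n_sessions + 1):
        probes = np.repeat(values, repeats)
        rng.shuffle(probes)
        p = response_probability(probes, protocol.test_numerosity, child.s_num, lapse)
        resp = rng.random(probes.size) < p
        for probe, r in zip(probes, resp):
            trials.append(
                TrialRecord2AFC(
                    child_id=child.child_id,
                    session=session,
                    probe=int(probe),
                    test=protocol.test_numerosity,
                    response_probe_greater=bool(r),
                )
            )
    return trials


def geometry_success_probability(
    g_geo: float, run: int, K: int, params: GeometryParams
) -> float:
    """First-attempt success probability for one scored location."""
    eta = (
        params.baseline
        + params.ability_slope * g_geo
        + params.run2_boost * (1.0 if run == 2 else 0.0)
        - params.complexity_cost * (K - K_MIN)
    )
    if np.isposinf(g_geo):
        return 1.0
    return float(params.guess + (1.0 - params.guess) * expit(eta))


def simulate_geometry_run(
    child: LatentChild,
    sequence: SpatialSequence,
    run: int,
    params: GeometryParams,
    rng: np.random.Generator,
) -> GeometryRunLog:
    """Simulate one run of one sequence for one child.

    Incorrect first attempts are followed by corrective restarts in the
    real task; restarted attempts are cued, carry no predictive signal and
    are not logged (the scoring layer only ever sees first attempts).
    """
    if run not in (1, 2):
        raise ConfigurationError(f"run must be 1 or 2, got {run!r}")
    n_targets = RUN1_PREDICTIONS if run == 1 else RUN2_PREDICTIONS
    start = len(sequence.positions) - n_targets
    p = geometry_success_probability(child.g_geo, run, sequence.K, params)
    entries = [
        (int(sequence.positions[start + i]), bool(rng.random() < p))
        for i in range(n_targets)
    ]
    return GeometryRunLog(
        child_id=child.child_id, sequence=sequence.name, run=run, entries=entries
    )


def simulate_battery(
    child: LatentChild,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    difficulties: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate the 8 + 24 three-option battery items of one child.

    P(correct) = 1/3 + (2/3) * logistic(f_formal - d_item): guessing floor
    of the three-option format plus a logistic ability-difficulty term.
    """
    diffs = difficulties or default_battery_difficulties(protocol)
    rows = []
    for factor in FACTORS:
        d = np.asarray(diffs[factor], dtype=float)
        p = 1.0 / 3.0 + (2.0 / 3.0) * expit(child.f_formal - d)
        correct = rng.random(d.size) < p
        for i in range(d.size):
            rows.append(
                {
                    "child_id": child.child_id,
                    "item_id": f"{factor}_{i + 1:02d}",
                    "factor": factor,
                    "grade": child.grade,
                    "correct": bool(correct[i]),
                }
            )
    return pd.DataFrame(rows)


def inject_missingness(
    battery: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop all battery rows of round(rate * n_children) children.

    The count of missing children is deterministic; which children are
    dropped depends on the generator state.  Returns the reduced table and
    the dropped ids.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError("missingness rate must lie in [0, 1]")
    ids = sorted(battery["child_id"].unique())
    n_missing = int(round(rate * len(ids)))
    dropped = sorted(rng.choice(ids, size=n_missing, replace=False).tolist())
    kept = battery[~battery["child_id"].isin(dropped)].reset_index(drop=True)
    return kept, dropped


# ---------------------------------------------------------------------------
# Whole-cohort simulation and CSV output
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """All simulated tables of one cohort."""

    children: pd.DataFrame       # child_id, age, grade, verbal_score
    numerosity_trials: pd.DataFrame
    geometry_log: pd.DataFrame
    battery_items: pd.DataFrame  # already missingness-reduced
    truth: pd.DataFrame          # ground-truth latents (never read by analyses)
    missing_battery: list[str]


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate latents and simulate all three tasks for every child."""
    children = generate_cohort(config)
    catalog = sequence_catalog()
    trials_rows, geo_rows, battery_frames = [], [], []
    for idx, child in enumerate(children):
        t_rng = substream(config.seed, "numerosity", idx)
        for t_i, tr in enumerate(
            simulate_numerosity_trials(child, config.protocol, t_rng, config.lapse)
        ):
            trials_rows.append(
                {
                    "child_id": tr.child_id,
                    "session": tr.session,
                    "trial_index": t_i,
                    "probe": tr.probe,
                    "test": tr.test,
                    "response_probe_greater": tr.response_probe_greater,
                }
            )
        g_rng = substream(config.seed, "geometry", idx)
        for seq in catalog:
            for run in (1, 2):
                log = simulate_geometry_run(child, seq, run, config.geometry, g_rng)
                for target, ok in log.entries:
                    geo_rows.append(
                        {
                            "child_id": child.child_id,
                            "sequence": seq.name,
                            "run": run,
                            "target_index": target,
                            "first_attempt_correct": ok,
                        }
                    )
        b_rng = substream(config.seed, "battery", idx)
        battery_frames.append(
            simulate_battery(child, config.protocol, b_rng, config.battery_difficulties)
        )
    battery = pd.concat(battery_frames, ignore_index=True)
    battery, dropped = inject_missingness(
        battery, config.missing_battery_rate, substream(config.seed, "missingness")
    )
    children_df = pd.DataFrame(
        {
            "child_id": [c.child_id for c in children],
            "age": [c.age for c in children],
            "grade": [c.grade for c in children],
            "verbal_score": [c.v_verbal for c in children],
        }
    )
    truth = pd.DataFrame(
        {
            "child_id": [c.child_id for c in children],
            "age": [c.age for c in children],
            "grade": [c.grade for c in children],
            "s_num": [c.s_num for c in children],
            "g_geo": [c.g_geo for c in children],
            "f_formal": [c.f_formal for c in children],
            "v_verbal": [c.v_verbal for c in children],
        }
    )
    return CohortData(
        children=children_df,
        numerosity_trials=pd.DataFrame(trials_rows),
        geometry_log=pd.DataFrame(geo_rows),
        battery_items=battery,
        truth=truth,
        missing_battery=dropped,
    )


def calibrate_norms(
    config: CohortConfig,
    n_children: int = 900,
    seed: int | None = None,
):
    """Derive a synthetic grade-wise norm table from a calibration cohort.

    The published battery's norm tables are proprietary, so z-scoring uses
    grade x factor raw-score means/SDs estimated from a large simulated
    cohort drawn under the same generative settings (battery intact, no
    missingness).  Children are simulated until every grade has data.
    """
    from dataclasses import replace as _replace

    from .scoring import NormTable, score_battery

    calib = _replace(
        config,
        n_children=n_children,
        missing_battery_rate=0.0,
        seed=seed if seed is not None else config.seed + 101,
    )
    children = generate_cohort(calib)
    rows = []
    for idx, child in enumerate(children):
        rng = substream(calib.seed, "norm-calibration", idx)
        items = simulate_battery(child, calib.protocol, rng, calib.battery_difficulties)
        raw = score_battery(items)
        rows.append(
            {
                "grade": child.grade,
                KNOWLEDGE: raw.knowledge_raw,
                VISUOSPATIAL: raw.visuospatial_raw,
            }
        )
    frame = pd.DataFrame(rows)
    cells = {}
    for grade, grp in frame.groupby("grade"):
        if len(grp) < 10:
            raise ConfigurationError(
                f"calibration cohort too small for grade {grade} ({len(grp)} children)"
            )
        for factor in FACTORS:
            cells[(int(grade), factor)] = (
                float(grp[factor].mean()),
                float(grp[factor].std(ddof=1)),
            )
    return NormTable(cells=cells)


CSV_NAMES = {
    "children": "children.csv",
    "numerosity_trials": "numerosity_trials.csv",
    "geometry_log": "geometry_log.csv",
    "battery_items": "battery_items.csv",
    "truth": "truth.csv",
}


def write_cohort_csvs(data: CohortData, outdir) -> dict[str, str]:
    """Write the four analysis tables plus truth.csv (UTF-8, '.' decimal)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in CSV_NAMES.items():
        frame: pd.DataFrame = getattr(data, attr)
        path = out / fname
        frame.to_csv(path, index=False)
        paths[attr] = str(path)
    return paths
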