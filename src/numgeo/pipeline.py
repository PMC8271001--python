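"""End-to-end pipeline: simulate -> score -> fit -> reliability -> inference.

A single :class:`RunConfig` (one master seed, serializable to JSON) drives
a reproducible run producing the study-shaped outputs: trial tables, a
child-scores table, psychometric fits, reliability estimates, the
correlation grid, the power analysis, and a descriptives table with one
column per measure (mean, SD, N).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    CohortData,
    GeometryParams,
    ProtocolConfig,
    calibrate_norms,
    simulate_cohort,
    write_cohort_csvs,
)
from .errors import ValidationError
from .inference import (
    CorrelationRequest,
    PowerQuery,
    correlation_report,
    paired_t,
    required_n_correlation,
)
from .psychometrics import FitOptions, estimate_sensitivity, fit_all
from .reliability import battery_item_matrix, bootstrap_split_half, cronbach_alpha
from .rng import spawn_seed
from .scoring import NormTable, score_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full specification of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    reliability_iterations: int = 10_000
    norm_calibration_n: int = 900
    combine_index: str = "mean"
    power: PowerQuery = field(
        default_factory=lambda: PowerQuery(effect_size_r=0.34, power=0.75, alpha=0.05, tails=1)
    )
    report_grid: list[CorrelationRequest] | None = None
    seed: int = 0


def mimic_table1_config(seed: int = 0) -> RunConfig:
    """Preset mirroring the reference cohort's printed descriptives
    (n=49, age 8-10.9, sensitivity mean 4.19 SD 1.39, 42 battery cases)."""
    return RunConfig(cohort=CohortConfig(seed=seed), seed=seed)


@dataclass
class RunReport:
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    reliability: dict[str, Any]
    power: dict[str, Any]
    run_comparison: dict[str, float]
    provenance: dict[str, Any]


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return encode(config)


def config_from_dict(d: Mapping) -> RunConfig:
    d = dict(d)
    cohort = dict(d.get("cohort", {}))
    if "protocol" in cohort:
        proto = dict(cohort["protocol"])
        cohort["protocol"] = ProtocolConfig(**proto)
    if "geometry" in cohort:
        cohort["geometry"] = GeometryParams(**cohort["geometry"])
    if "trait_corr" in cohort:
        cohort["trait_corr"] = np.asarray(cohort["trait_corr"], dtype=float)
    if "age_range" in cohort:
        cohort["age_range"] = tuple(cohort["age_range"])
    if "grade_thresholds" in cohort:
        cohort["grade_thresholds"] = tuple(cohort["grade_thresholds"])
    if cohort.get("battery_difficulties") is not None:
        cohort["battery_difficulties"] = {
            k: np.asarray(v, dtype=float)
            for k, v in cohort["battery_difficulties"].items()
        }
    grid = d.get("report_grid")
    return RunConfig(
        cohort=CohortConfig(**cohort),
        fit=FitOptions(**d.get("fit", {})),
        reliability_iterations=int(d.get("reliability_iterations", 10_000)),
        norm_calibration_n=int(d.get("norm_calibration_n", 900)),
        combine_index=d.get("combine_index", "mean"),
        power=PowerQuery(**d.get("power", {})) if "power" in d else RunConfig().power,
        report_grid=(
            [CorrelationRequest(g["x"], g["y"], tuple(g.get("covariates", ()))) for g in grid]
            if grid is not None
            else None
        ),
        seed=int(d.get("seed", 0)),
    )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Loading and validation of user-supplied tables
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, dict[str, str]] = {
    "children": {
        "child_id": "str", "age": "float", "grade": "int", "verbal_score": "float",
    },
    "numerosity_trials": {
        "child_id": "str", "session": "int", "trial_index": "int",
        "probe": "int", "test": "int", "response_probe_greater": "bool",
    },
    "geometry_log": {
        "child_id": "str", "sequence": "str", "run": "int",
        "target_index": "int", "first_attempt_correct": "bool",
    },
    "battery_items": {
        "child_id": "str", "item_id": "str", "factor": "str", "correct": "bool",
    },
}


def _validate_frame(name: str, frame: pd.DataFrame) -> pd.DataFrame:
    schema = _SCHEMAS[name]
    missing = set(schema) - set(frame.columns)
    if missing:
        raise ValidationError(f"{name}: missing column(s) {sorted(missing)}")
    for col, kind in schema.items():
        series = frame[col]
        if kind in ("int", "float"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                rows = list(frame.index[bad][:5])
                raise ValidationError(
                    f"{name}: non-numeric values in column {col!r} at rows {rows}"
                )
            frame[col] = coerced.astype(float if kind == "float" else "Int64")
        elif kind == "bool":
            mapped = series.map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            bad = mapped.isna() & series.notna()
            if bad.any():
                rows = list(frame.index[bad][:5])
                raise ValidationError(
                    f"{name}: non-boolean values in column {col!r} at rows {rows}"
                )
            frame[col] = mapped.astype(bool)
    if name == "numerosity_trials":
        bad = frame.index[(frame["probe"] < 3) | (frame["probe"] > 16)]
        if len(bad):
            raise ValidationError(
                f"numerosity_trials: probe outside the protocol bound [3, 16] "
                f"at rows {list(bad[:5])}"
            )
    if name == "geometry_log":
        bad = frame.index[~frame["run"].isin([1, 2])]
        if len(bad):
            raise ValidationError(f"geometry_log: run must be 1 or 2 at rows {list(bad[:5])}")
    return frame


def load_cohort(data_dir) -> dict[str, pd.DataFrame | None]:
    """Load and schema-validate the four analysis tables from a directory.

    A missing battery file is tolerated (battery analyses are skipped with
    a logged notice); the other three tables are required.
    """
    data_dir = Path(data_dir)
    tables: dict[str, pd.DataFrame | None] = {}
    for name in ("children", "numerosity_trials", "geometry_log"):
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise ValidationError(f"required table missing: {path}")
        tables[name] = _validate_frame(name, pd.read_csv(path))
    battery_path = data_dir / "battery_items.csv"
    if battery_path.exists():
        tables["battery_items"] = _validate_frame("battery_items", pd.read_csv(battery_path))
    else:
        logger.info("battery_items.csv absent: battery analyses will be skipped")
        tables["battery_items"] = None
    return tables


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _descriptives(scores: pd.DataFrame, children: pd.DataFrame) -> pd.DataFrame:
    merged = scores.merge(children, on="child_id", how="left")
    cols = [
        "age", "verbal_score", "sensitivity", "acc_run1", "acc_run2",
        "z_knowledge", "z_visuospatial", "combined_index",
    ]
    rows = {
        "mean": [merged[c].mean() for c in cols],
        "sd": [merged[c].std(ddof=1) for c in cols],
        "n": [int(merged[c].notna().sum()) for c in cols],
    }
    return pd.DataFrame(rows, index=cols).T


def run_pipeline(
    config: RunConfig,
    outdir=None,
    data: CohortData | Mapping[str, pd.DataFrame | None] | None = None,
) -> RunReport:
    """Execute all stages deterministically under the master seed.

    ``data`` may supply pre-loaded tables (from :func:`load_cohort`);
    otherwise a cohort is simulated from ``config.cohort``.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if data is None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.cohort.seed or config.seed)
        sim = simulate_cohort(cohort_cfg)
        children, trials = sim.children, sim.numerosity_trials
        geometry, battery = sim.geometry_log, sim.battery_items
        if out is not None:
            write_cohort_csvs(sim, out)
    elif isinstance(data, CohortData):
        children, trials = data.children, data.numerosity_trials
        geometry, battery = data.geometry_log, data.battery_items
    else:
        children = data["children"]
        trials = data["numerosity_trials"]
        geometry = data["geometry_log"]
        battery = data.get("battery_items")

    # --- psychometric fits -------------------------------------------------
    logger.info("fitting psychometric functions")
    fits = fit_all(trials, config.fit)
    if out is not None:
        fits.to_csv(out / "fits.csv", index=False)

    # --- scoring -----------------------------------------------------------
    logger.info("scoring geometry and battery")
    norms: NormTable | None = None
    if battery is not None and len(battery):
        norms = calibrate_norms(
            config.cohort,
            n_children=config.norm_calibration_n,
            seed=spawn_seed(config.seed, "norms"),
        )
    grades = dict(zip(children["child_id"].astype(str), children["grade"].astype(int)))
    scores = score_all(geometry, battery, norms, grades, combine=config.combine_index)
    scores = scores.merge(fits[["child_id", "sensitivity"]], on="child_id", how="left")
    if out is not None:
        scores.to_csv(out / "child_scores.csv", index=False)

    # --- reliability -------------------------------------------------------
    logger.info("reliability (%d bootstrap iterations)", config.reliability_iterations)
    trials_by_child = {
        str(cid): (grp["probe"].to_numpy(float), grp["response_probe_greater"].to_numpy(bool))
        for cid, grp in trials.groupby("child_id")
    }
    boot = bootstrap_split_half(
        trials_by_child,
        lambda t: estimate_sensitivity(t, config.fit),
        n_iter=config.reliability_iterations,
        seed=spawn_seed(config.seed, "bootstrap"),
    )
    reliability: dict[str, Any] = {
        "sensitivity_split_half": {
            "mean_r": boot.mean_r,
            "se_r": boot.se_r,
            "n_iterations": boot.n_iterations,
            "n_children": boot.n_children,
            "n_estimator_failures": boot.n_estimator_failures,
        }
    }
    if battery is not None and len(battery):
        for factor in ("knowledge", "visuospatial"):
            mat = battery_item_matrix(battery, factor)
            a = cronbach_alpha(mat)
            reliability[f"alpha_{factor}"] = {
                "alpha": a.alpha, "ci_low": a.ci_low, "ci_high": a.ci_high,
                "n_items": a.n_items, "n_subjects": a.n_subjects,
            }
    if out is not None:
        (out / "reliability.json").write_text(
            json.dumps({"seed": config.seed, "results": reliability}, indent=2)
        )

    # --- inference ---------------------------------------------------------
    logger.info("correlation grid and power analysis")
    merged = scores.merge(children[["child_id", "age", "verbal_score"]], on="child_id", how="left")
    grid = config.report_grid
    if grid is None and (battery is None or not len(battery)):
        from .inference import default_report_grid

        grid = [r for r in default_report_grid() if "combined_index" not in (r.x, r.y)]
        logger.info("battery absent: combined-index correlations skipped")
    correlations = correlation_report(merged, grid)
    if out is not None:
        correlations.to_csv(out / "correlations.csv", index=False)

    t_val, t_df, t_p = paired_t(merged["acc_run2"], merged["acc_run1"])
    run_comparison = {"t": t_val, "df": t_df, "p": t_p}

    n_required = required_n_correlation(config.power)
    power = {
        "effect_size_r": config.power.effect_size_r,
        "power": config.power.power,
        "alpha": config.power.alpha,
        "tails": config.power.tails,
        "required_n": n_required,
    }
    if out is not None:
        (out / "power.json").write_text(json.dumps(power, indent=2))

    report = RunReport(
        descriptives=_descriptives(scores, children),
        correlations=correlations,
        reliability=reliability,
        power=power,
        run_comparison=run_comparison,
        provenance={
            "config_hash": config_hash(config),
            "seed": config.seed,
            "numgeo_version": __version__,
        },
    )
    if out is not None:
        (out / "report.json").write_text(report_to_json(report))
    return report


def report_to_json(report: RunReport) -> str:
    payload = {
        "descriptives": report.descriptives.round(10).to_dict(),
        "correlations": report.correlations.round(10).to_dict(orient="records"),
        "reliability": report.reliability,
        "power": report.power,
        "run_comparison": report.run_comparison,
        "provenance": report.provenance,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
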