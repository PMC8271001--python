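"""Scoring of the geometric-sequence task and the formal geometry battery.

The sequence task shows a character jumping over eight positions of an
octagonal grid following a geometric rule; the child predicts upcoming
positions.  Each sequence is tested in two consecutive runs: in run 1 the
first five positions are shown and the child predicts the next three; in
run 2 only the first three are cued and the child reproduces the remaining
five.  A wrong press triggers a corrective restart, so only *first*
attempts at each target position carry information about prediction and
only they are scored.  Performance per run is the proportion of correct
first attempts.

The formal battery has two factors — geometry knowledge (8 three-option
questions) and visuo-spatial abilities (24 three-option items).  Raw counts
per factor are z-scored against grade-specific norms and averaged into a
combined index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CatalogError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

RUN1_PREDICTIONS = 3
RUN2_PREDICTIONS = 5
N_GRID_POSITIONS = 8

KNOWLEDGE = "knowledge"
VISUOSPATIAL = "visuospatial"
FACTORS = (KNOWLEDGE, VISUOSPATIAL)


# ---------------------------------------------------------------------------
# Sequence catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialSequence:
    """One spatial configuration of the sequence-prediction task.

    ``K`` is an imported minimal-description-length complexity constant
    (higher = less regular).  ``block_index`` is the fixed presentation
    order (easiest first).  ``positions`` lists the 8 visited grid indices;
    only the ``repeat`` walk is documented exactly (clockwise +1 steps), the
    other position lists are plausible placeholders and may be overridden.
    """

    name: str
    positions: tuple[int, ...]
    K: int
    block_index: int

    def __post_init__(self) -> None:
        if len(self.positions) != N_GRID_POSITIONS:
            raise ConfigurationError(
                f"sequence {self.name!r}: expected {N_GRID_POSITIONS} positions, "
                f"got {len(self.positions)}"
            )
        if any(not (0 <= p < N_GRID_POSITIONS) for p in self.positions):
            raise ConfigurationError(
                f"sequence {self.name!r}: positions must lie in 0..7"
            )


# name -> (K, block order).  Fixed; not configurable.
_CATALOG_SPEC: tuple[tuple[str, int], ...] = (
    ("repeat", 5),
    ("repeat+2", 7),
    ("2arcs", 8),
    ("squares", 8),
    ("segments", 7),
    ("diagonals", 7),
    ("rectangles", 10),
    ("crosses", 7),
)

K_MIN = min(k for _, k in _CATALOG_SPEC)

# Placeholder position walks (the exact orders are shown only graphically in
# the source task); "repeat" is the documented clockwise +1 walk.
_DEFAULT_POSITIONS: dict[str, tuple[int, ...]] = {
    "repeat": (0, 1, 2, 3, 4, 5, 6, 7),
    "repeat+2": (2, 3, 4, 5, 6, 7, 0, 1),
    "2arcs": (0, 1, 2, 3, 7, 6, 5, 4),
    "squares": (0, 2, 4, 6, 1, 3, 5, 7),
    "segments": (0, 4, 1, 5, 2, 6, 3, 7),
    "diagonals": (1, 5, 2, 6, 3, 7, 4, 0),
    "rectangles": (0, 1, 4, 5, 2, 3, 6, 7),
    "crosses": (0, 4, 2, 6, 5, 1, 7, 3),
}


def sequence_catalog(
    positions: Mapping[str, Sequence[int]] | None = None,
) -> tuple[SpatialSequence, ...]:
    """Return the 8 spatial sequences in their fixed block order.

    ``positions`` may override the position walks per sequence name; names,
    complexity constants and presentation order are immutable.
    """
    overrides = dict(positions or {})
    unknown = set(overrides) - {name for name, _ in _CATALOG_SPEC}
    if unknown:
        raise CatalogError(f"unknown sequence name(s): {sorted(unknown)}")
    out = []
    for block, (name, k) in enumerate(_CATALOG_SPEC, start=1):
        pos = tuple(overrides.get(name, _DEFAULT_POSITIONS[name]))
        out.append(SpatialSequence(name=name, positions=pos, K=k, block_index=block))
    return tuple(out)


def get_sequence(name: str, catalog: Sequence[SpatialSequence] | None = None) -> SpatialSequence:
    for seq in catalog or sequence_catalog():
        if seq.name == name:
            return seq
    raise CatalogError(f"unknown sequence name: {name!r}")


# ---------------------------------------------------------------------------
# Geometry-run scoring
# ---------------------------------------------------------------------------

@dataclass
class GeometryRunLog:
    """First-attempt correctness at each scored target of one run."""

    child_id: str
    sequence: str
    run: int
    entries: list[tuple[int, bool]]  # (target position index, correct)


def _expected_entries(run: int) -> int:
    if run == 1:
        return RUN1_PREDICTIONS
    if run == 2:
        return RUN2_PREDICTIONS
    raise ValidationError(f"run must be 1 or 2, got {run!r}")


def score_geometry_run(log: GeometryRunLog) -> float:
    """Proportion of correct first attempts in one run of one sequence.

    Re-attempts after the corrective restart are cued and never appear in
    the log, hence never contribute.
    """
    expected = _expected_entries(log.run)
    if len(log.entries) != expected:
        raise ValidationError(
            f"child {log.child_id!r}, sequence {log.sequence!r}, run {log.run}: "
            f"expected {expected} scored entries, got {len(log.entries)}"
        )
    return float(np.mean([bool(c) for _, c in log.entries]))


@dataclass
class GeometryAccuracy:
    acc_run1: float
    acc_run2: float
    acc_overall: float
    n_run1: int
    n_run2: int


def aggregate_geometry(logs: Iterable[GeometryRunLog]) -> GeometryAccuracy:
    """Per-child accuracies: run 1 (24 responses), run 2 (40), overall (64).

    Overall accuracy is the response-weighted mean of the run accuracies.
    Missing sequences are tolerated with a logged warning; denominators
    adjust to the responses actually present.
    """
    logs = list(logs)
    if not logs:
        raise ValidationError("no geometry logs supplied")
    runs_present = {log.run for log in logs}
    if runs_present != {1, 2}:
        raise ValidationError(f"logs must cover both runs, found runs {sorted(runs_present)}")
    catalog_names = {name for name, _ in _CATALOG_SPEC}
    seen = {log.sequence for log in logs}
    missing = catalog_names - seen
    if missing:
        logger.warning(
            "child %s: missing sequences %s; accuracy denominators adjusted",
            logs[0].child_id, sorted(missing),
        )
    correct = {1: 0, 2: 0}
    total = {1: 0, 2: 0}
    for log in logs:
        score_geometry_run(log)  # validates entry counts
        correct[log.run] += sum(bool(c) for _, c in log.entries)
        total[log.run] += len(log.entries)
    acc1 = correct[1] / total[1]
    acc2 = correct[2] / total[2]
    overall = (correct[1] + correct[2]) / (total[1] + total[2])
    return GeometryAccuracy(acc1, acc2, overall, total[1], total[2])


# ---------------------------------------------------------------------------
# Battery scoring
# ---------------------------------------------------------------------------

@dataclass
class BatteryScores:
    """Raw and normed scores of the formal geometry battery for one child."""

    child_id: str
    grade: int
    knowledge_raw: int
    visuospatial_raw: int
    z_knowledge: float | None = None
    z_visuospatial: float | None = None
    combined_index: float | None = None


@dataclass(frozen=True)
class NormTable:
    """Grade- and factor-wise raw-score means and SDs used for z-scoring.

    The published manual's norm tables are proprietary; these are synthetic
    fixtures, typically derived from a large simulated calibration cohort.
    """

    cells: Mapping[tuple[int, str], tuple[float, float]]  # (grade, factor) -> (mean, sd)

    def __post_init__(self) -> None:
        for (grade, factor), (mean, sd) in self.cells.items():
            if sd <= 0:
                raise ConfigurationError(
                    f"norm SD must be positive for grade {grade}, factor {factor!r}"
                )

    def lookup(self, grade: int, factor: str) -> tuple[float, float]:
        try:
            return self.cells[(grade, factor)]
        except KeyError:
            raise ConfigurationError(
                f"no norms for grade {grade}, factor {factor!r}"
            ) from None


def score_battery(
    items: pd.DataFrame,
    *,
    n_knowledge: int = 8,
    n_visuospatial: int = 24,
) -> BatteryScores:
    """Count correct responses per factor for one child.

    ``items`` needs columns child_id, item_id, factor, correct and must be
    a complete vector (all items answered); incomplete children are flagged
    upstream for pairwise exclusion.
    """
    if items.empty:
        raise ValidationError("empty battery item vector")
    child_ids = items["child_id"].unique()
    if len(child_ids) != 1:
        raise ValidationError(f"expected items of one child, got {list(child_ids)}")
    counts = items.groupby("factor").size().to_dict()
    expected = {KNOWLEDGE: n_knowledge, VISUOSPATIAL: n_visuospatial}
    if counts != expected:
        raise ValidationError(
            f"child {child_ids[0]!r}: incomplete battery vector {counts}, "
            f"expected {expected}; child must be flagged missing"
        )
    grade = int(items["grade"].iloc[0]) if "grade" in items else -1
    by_factor = items.groupby("factor")["correct"].sum().to_dict()
    return BatteryScores(
        child_id=str(child_ids[0]),
        grade=grade,
        knowledge_raw=int(by_factor[KNOWLEDGE]),
        visuospatial_raw=int(by_factor[VISUOSPATIAL]),
    )


def z_transform(
    scores: BatteryScores,
    norms: NormTable,
    *,
    grade: int | None = None,
    combine: str = "mean",
) -> BatteryScores:
    """Z-score raw factor counts against grade norms and form the combined index.

    The combined index defaults to the *mean* of the two factor z-scores
    (``combine="sum"`` is available).
    """
    if combine not in ("mean", "sum"):
        raise ConfigurationError(f"combine must be 'mean' or 'sum', got {combine!r}")
    g = scores.grade if grade is None else grade
    mk, sk = norms.lookup(g, KNOWLEDGE)
    mv, sv = norms.lookup(g, VISUOSPATIAL)
    zk = (scores.knowledge_raw - mk) / sk
    zv = (scores.visuospatial_raw - mv) / sv
    combined = (zk + zv) / 2 if combine == "mean" else zk + zv
    return replace(
        scores, grade=g, z_knowledge=zk, z_visuospatial=zv, combined_index=combined
    )


# ---------------------------------------------------------------------------
# Table-level helpers used by the pipeline
# ---------------------------------------------------------------------------

def geometry_logs_from_frame(frame: pd.DataFrame) -> dict[str, list[GeometryRunLog]]:
    """Group a geometry_log table (child_id, sequence, run, target_index,
    first_attempt_correct) into per-child run logs."""
    out: dict[str, list[GeometryRunLog]] = {}
    cols = ["child_id", "sequence", "run"]
    for (cid, seq, run), grp in frame.groupby(cols, sort=True):
        grp = grp.sort_values("target_index")
        entries = [
            (int(t), bool(c))
            for t, c in zip(grp["target_index"], grp["first_attempt_correct"])
        ]
        out.setdefault(str(cid), []).append(
            GeometryRunLog(child_id=str(cid), sequence=str(seq), run=int(run), entries=entries)
        )
    return out


def score_all(
    geometry: pd.DataFrame,
    battery: pd.DataFrame | None,
    norms: NormTable | None,
    grades: Mapping[str, int] | None = None,
    *,
    combine: str = "mean",
) -> pd.DataFrame:
    """Build the child_scores table from trial-level logs.

    Battery columns are NaN for children without (complete) battery data,
    so downstream correlations handle them by pairwise deletion.
    """
    rows = []
    logs_by_child = geometry_logs_from_frame(geometry)
    battery_by_child: dict[str, pd.DataFrame] = {}
    if battery is not None and not battery.empty:
        battery_by_child = {str(c): g for c, g in battery.groupby("child_id")}
    for cid in sorted(logs_by_child):
        acc = aggregate_geometry(logs_by_child[cid])
        row = {
            "child_id": cid,
            "acc_run1": acc.acc_run1,
            "acc_run2": acc.acc_run2,
            "acc_overall": acc.acc_overall,
            "knowledge_raw": np.nan,
            "visuospatial_raw": np.nan,
            "z_knowledge": np.nan,
            "z_visuospatial": np.nan,
            "combined_index": np.nan,
        }
        items = battery_by_child.get(cid)
        if items is not None and norms is not None:
            try:
                raw = score_battery(items)
                grade = grades[cid] if grades else raw.grade
                scored = z_transform(raw, norms, grade=grade, combine=combine)
            except ValidationError as exc:
                logger.warning("battery skipped: %s", exc)
            else:
                row.update(
                    knowledge_raw=scored.knowledge_raw,
                    visuospatial_raw=scored.visuospatial_raw,
                    z_knowledge=scored.z_knowledge,
                    z_visuospatial=scored.z_visuospatial,
                    combined_index=scored.combined_index,
                )
        rows.append(row)
    return pd.DataFrame(rows)
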