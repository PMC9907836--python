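"""Cohort assembly: CVP series container, inclusion/exclusion, truncation.

Selection rules for the septic cohort: a patient is kept iff a CVP series
exists, the first measurement falls within ``start_limit_hr`` of ICU
admission, monitoring extends to at least ``window_hr`` (judged on the full,
untruncated stream), and age is at least ``min_age_years``. Analysis then
uses only the measurements with time <= ``window_hr`` (inclusive boundary,
no interpolation at the cut).

Exclusion reasons are reported with a fixed precedence — no-CVP, age, late
start, early end — so flowchart counts are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CohortConfig

__all__ = [
    "CVPSeries",
    "SelectionReport",
    "EmptySeriesError",
    "select_patients",
    "truncate_series",
    "clean_values",
    "read_cvp_events",
    "read_patients",
    "write_cvp_events",
    "write_patients",
    "EVENT_COLUMNS",
    "PATIENT_COLUMNS",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["patient_id", "time_hr", "cvp_mmhg"]

#: Canonical patient-table column order (one row per patient).
PATIENT_COLUMNS = [
    "patient_id", "age", "female", "weight", "sofa", "sapsii",
    "chf", "liver_mild", "liver_severe", "renal", "diabetes", "cancer",
    "lactate_max", "creatinine_max", "hemoglobin_min", "platelet_min",
    "inr_max", "map_min", "temp_mean", "spo2_min",
    "intake_72h_ml", "urine_72h_ml", "aki", "death_28d", "survival_days",
]

#: Minimum patient-table columns the pipeline needs to run.
PATIENT_REQUIRED = ["patient_id", "age", "death_28d", "survival_days"]


class EmptySeriesError(ValueError):
    """An operation would produce or received an empty CVP series."""


@dataclass(frozen=True)
class CVPSeries:
    """One patient's irregular CVP stream on the hours-from-admission axis.

    ``times`` are strictly increasing, non-negative hours; ``values`` are
    CVP in mmHg, one per time point.
    """

    patient_id: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError(
                f"patient {self.patient_id}: times and values must be equal-length 1-D arrays"
            )
        if t.size < 1:
            raise EmptySeriesError(f"patient {self.patient_id}: empty series")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError(f"patient {self.patient_id}: non-finite entries")
        if t[0] < 0:
            raise ValueError(f"patient {self.patient_id}: negative time")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"patient {self.patient_id}: times must be strictly increasing"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SelectionReport:
    """Flowchart bookkeeping for cohort selection."""

    n_input: int = 0
    n_excluded_no_cvp: int = 0
    n_excluded_age: int = 0
    n_excluded_late_start: int = 0
    n_excluded_early_end: int = 0
    n_included: int = 0
    reasons: Dict[int, str] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.n_included
            + self.n_excluded_no_cvp
            + self.n_excluded_age
            + self.n_excluded_late_start
            + self.n_excluded_early_end
        )
        if total != self.n_input:
            raise AssertionError(
                f"selection counts do not reconcile: {total} != {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_no_cvp": self.n_excluded_no_cvp,
            "n_excluded_age": self.n_excluded_age,
            "n_excluded_late_start": self.n_excluded_late_start,
            "n_excluded_early_end": self.n_excluded_early_end,
            "n_included": self.n_included,
            "reasons": {str(k): v for k, v in sorted(self.reasons.items())},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def select_patients(
    series_list: Sequence[CVPSeries],
    records: pd.DataFrame,
    cfg: CohortConfig | None = None,
) -> Tuple[List[CVPSeries], pd.DataFrame, SelectionReport]:
    """Apply inclusion/exclusion rules; return kept series, records, report.

    A record without a matching series counts as a no-CVP exclusion, not an
    error. Selection judges the *untruncated* stream: first time must be
    <= start_limit_hr and last time >= window_hr.
    """
    cfg = cfg or CohortConfig()
    if "patient_id" not in records.columns:
        raise ValueError("records table lacks a patient_id column")
    by_id = {s.patient_id: s for s in series_list}
    orphans = set(by_id) - set(records["patient_id"])
    if orphans:
        logger.warning(
            "%d CVP series without a patient record are ignored", len(orphans)
        )

    report = SelectionReport(n_input=len(records))
    kept_ids: List[int] = []
    for pid, age in zip(records["patient_id"], records["age"]):
        s = by_id.get(pid)
        if s is None:
            report.n_excluded_no_cvp += 1
            report.reasons[pid] = "no_cvp"
        elif age < cfg.min_age_years:
            report.n_excluded_age += 1
            report.reasons[pid] = "age"
        elif s.times[0] > cfg.start_limit_hr:
            report.n_excluded_late_start += 1
            report.reasons[pid] = "late_start"
        elif s.times[-1] < cfg.window_hr:
            report.n_excluded_early_end += 1
            report.reasons[pid] = "early_end"
        else:
            kept_ids.append(pid)
    report.n_included = len(kept_ids)
    report.check()

    kept_set = set(kept_ids)
    kept_series = [by_id[pid] for pid in kept_ids]
    kept_records = records[records["patient_id"].isin(kept_set)].reset_index(drop=True)
    return kept_series, kept_records, report


def truncate_series(s: CVPSeries, cfg: CohortConfig | None = None) -> CVPSeries:
    """Keep exactly the measurements with time <= window (inclusive).

    No boundary interpolation is performed; values are untouched.
    """
    cfg = cfg or CohortConfig()
    mask = s.times <= cfg.window_hr
    if not mask.any():
        raise EmptySeriesError(
            f"patient {s.patient_id}: no measurements within {cfg.window_hr} h"
        )
    if mask.all():
        return s
    return CVPSeries(s.patient_id, s.times[mask], s.values[mask])


def clean_values(s: CVPSeries, cfg: CohortConfig | None = None) -> CVPSeries:
    """Drop physiologically implausible measurements (artifact bounds)."""
    cfg = cfg or CohortConfig()
    mask = (s.values >= cfg.value_floor_mmhg) & (s.values <= cfg.value_ceiling_mmhg)
    n_dropped = int((~mask).sum())
    if n_dropped == 0:
        return s
    logger.info(
        "patient %s: dropped %d out-of-range CVP values", s.patient_id, n_dropped
    )
    if not mask.any():
        raise EmptySeriesError(
            f"patient {s.patient_id}: all values outside "
            f"[{cfg.value_floor_mmhg}, {cfg.value_ceiling_mmhg}] mmHg"
        )
    return CVPSeries(s.patient_id, s.times[mask], s.values[mask])


# ---------------------------------------------------------------------------
# CSV ingest / export


def read_cvp_events(path: str | Path) -> List[CVPSeries]:
    """Read the long-format measurement table into per-patient series.

    Rows are sorted by (patient_id, time_hr); duplicate timestamps within a
    patient are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.sort_values(["patient_id", "time_hr"], kind="mergesort")
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        out.append(
            CVPSeries(int(pid), grp["time_hr"].to_numpy(), grp["cvp_mmhg"].to_numpy())
        )
    return out


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient_id rows")
    return df


def write_cvp_events(series_list: Iterable[CVPSeries], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"patient_id": s.patient_id, "time_hr": s.times, "cvp_mmhg": s.values}
        )
        for s in sorted(series_list, key=lambda s: s.patient_id)
    ]
    if not frames:
        raise EmptySeriesError("no series to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_patients(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in PATIENT_COLUMNS if c in records.columns] + [
        c for c in records.columns if c not in PATIENT_COLUMNS
    ]
    records[cols].sort_values("patient_id").to_csv(path, index=False)
    return path
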