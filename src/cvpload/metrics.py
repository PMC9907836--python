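"""Trapezoidal CVP exposure metrics on irregularly sampled series.

The exposure calculus works on the piecewise-linear interpolant of a
patient's CVP measurements. Each pair of adjacent measurements defines a
*segment* with trapezoid area ``(v_i + v_{i+1})/2 * (t_{i+1} - t_i)``
(mmHg·hr). A segment is *elevated* (ECVP) when its endpoint-mean CVP is
strictly above the threshold (default 10 mmHg); the whole segment is
classified by that mean — no interpolated threshold-crossing points.

Derived quantities for a series with measurements at t_1 < ... < t_N:

==============================  =============================================
CVP duration (hr)               t_N - t_1
CVP load (mmHg·hr)              sum of all segment areas
ECVP duration (hr)              sum of elevated segment lengths
ECVP load (mmHg·hr)             sum of elevated segment areas (full
                                trapezoids, not the excess above threshold)
normalized CVP load (mmHg)      CVP load / CVP duration
normalized ECVP load (mmHg)     ECVP load / ECVP duration (0 and flagged
                                undefined when no segment is elevated)
averaged ECVP load (mmHg)       ECVP load / CVP duration
% ECVP duration                 100 * ECVP duration / CVP duration
==============================  =============================================

Normalized loads are time-weighted average pressures, which is what makes
irregularly sampled streams comparable across patients. The ECVP load is
the full area under the curve during elevated segments — so the normalized
ECVP load is the time-weighted mean CVP *while elevated* (always above the
threshold when defined), not the mean exceedance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CVPSeries
from .config import CohortConfig

__all__ = [
    "Segment",
    "ExposureMetrics",
    "DegenerateSeriesError",
    "build_segments",
    "compute_metrics",
    "compute_cohort_metrics",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "patient_id",
    "cvp_duration_hr",
    "ecvp_duration_hr",
    "cvp_load",
    "ecvp_load",
    "norm_cvp_load",
    "norm_ecvp_load",
    "avg_ecvp_load",
    "pct_ecvp_duration",
    "norm_ecvp_defined",
]


class DegenerateSeriesError(ValueError):
    """Series too short for exposure metrics (fewer than two measurements)."""

    def __init__(self, patient_id: int):
        self.patient_id = patient_id
        super().__init__(
            f"patient {patient_id}: need >= 2 CVP measurements for exposure metrics"
        )


@dataclass(frozen=True)
class Segment:
    """One inter-measurement interval of the piecewise-linear CVP curve."""

    t_start: float
    t_end: float
    v_start: float
    v_end: float
    mean_cvp: float
    is_ecvp: bool
    area: float


@dataclass(frozen=True)
class ExposureMetrics:
    patient_id: int
    cvp_duration_hr: float
    ecvp_duration_hr: float
    cvp_load_mmhg_hr: float
    ecvp_load_mmhg_hr: float
    normalized_cvp_load_mmhg: float
    normalized_ecvp_load_mmhg: float
    averaged_ecvp_load_mmhg: float
    pct_ecvp_duration: float
    norm_ecvp_defined: bool

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "cvp_duration_hr": self.cvp_duration_hr,
            "ecvp_duration_hr": self.ecvp_duration_hr,
            "cvp_load": self.cvp_load_mmhg_hr,
            "ecvp_load": self.ecvp_load_mmhg_hr,
            "norm_cvp_load": self.normalized_cvp_load_mmhg,
            "norm_ecvp_load": self.normalized_ecvp_load_mmhg,
            "avg_ecvp_load": self.averaged_ecvp_load_mmhg,
            "pct_ecvp_duration": self.pct_ecvp_duration,
            "norm_ecvp_defined": self.norm_ecvp_defined,
        }


def _segment_arrays(
    times: np.ndarray, values: np.ndarray, threshold: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized segment decomposition: (lengths, means, areas, elevated)."""
    dt = np.diff(times)
    means = 0.5 * (values[:-1] + values[1:])
    areas = means * dt
    elevated = means > threshold  # strict: a mean exactly at threshold is not ECVP
    return dt, means, areas, elevated


def build_segments(s: CVPSeries, threshold: float = 10.0) -> List[Segment]:
    """Decompose a series into its N-1 contiguous classified segments."""
    if len(s) < 2:
        raise DegenerateSeriesError(s.patient_id)
    dt, means, areas, elevated = _segment_arrays(s.times, s.values, threshold)
    return [
        Segment(
            t_start=float(s.times[i]),
            t_end=float(s.times[i + 1]),
            v_start=float(s.values[i]),
            v_end=float(s.values[i + 1]),
            mean_cvp=float(means[i]),
            is_ecvp=bool(elevated[i]),
            area=float(areas[i]),
        )
        for i in range(dt.size)
    ]


def compute_metrics(s: CVPSeries, threshold: float = 10.0) -> ExposureMetrics:
    """Compute the exposure metrics of one (already truncated) series.

    The total load is accumulated as elevated + non-elevated partial sums, so
    the decomposition ``cvp_load == ecvp_load + non-elevated area`` holds
    exactly, not merely to rounding.
    """
    if len(s) < 2:
        raise DegenerateSeriesError(s.patient_id)
    dt, _, areas, elevated = _segment_arrays(s.times, s.values, threshold)

    ecvp_load = float(areas[elevated].sum())
    non_ecvp_load = float(areas[~elevated].sum())
    cvp_load = ecvp_load + non_ecvp_load
    cvp_duration = float(s.times[-1] - s.times[0])
    ecvp_duration = float(dt[elevated].sum())

    defined = ecvp_duration > 0.0
    norm_ecvp = ecvp_load / ecvp_duration if defined else 0.0
    return ExposureMetrics(
        patient_id=s.patient_id,
        cvp_duration_hr=cvp_duration,
        ecvp_duration_hr=ecvp_duration,
        cvp_load_mmhg_hr=cvp_load,
        ecvp_load_mmhg_hr=ecvp_load,
        normalized_cvp_load_mmhg=cvp_load / cvp_duration,
        normalized_ecvp_load_mmhg=norm_ecvp,
        averaged_ecvp_load_mmhg=ecvp_load / cvp_duration,
        pct_ecvp_duration=100.0 * ecvp_duration / cvp_duration,
        norm_ecvp_defined=defined,
    )


def compute_cohort_metrics(
    series_list: Sequence[CVPSeries],
    cfg: CohortConfig | None = None,
) -> Tuple[pd.DataFrame, Dict[int, str]]:
    """Exposure metrics for every patient; one row each, ordered by id.

    Degenerate series are reported in the returned failure map (id ->
    message) and the remaining patients are still computed.
    """
    cfg = cfg or CohortConfig()
    rows = []
    failures: Dict[int, str] = {}
    for s in sorted(series_list, key=lambda s: s.patient_id):
        try:
            rows.append(compute_metrics(s, cfg.ecvp_threshold_mmhg).to_row())
        except DegenerateSeriesError as exc:
            failures[s.patient_id] = str(exc)
    if failures:
        logger.warning(
            "exposure metrics skipped for %d degenerate series", len(failures)
        )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return df, failures
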