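"""Seeded synthetic septic ICU cohorts for exercising the exposure pipeline.

The generator emulates the statistical structure the analysis assumes,
without any access to clinical databases:

* irregular CVP sampling — a monitoring start uniform on [0, 24] h, an end
  uniform on [72, 96] h, exponential inter-measurement gaps (mean 1 h) and
  independent per-measurement dropout;
* autocorrelated CVP — patient setpoint plus a discretized
  Ornstein–Uhlenbeck fluctuation evaluated exactly at the irregular
  measurement times, floored at 0 mmHg and charted to 0.1 mmHg;
* a logistic 28-day mortality link on the normalized elevated-CVP load plus
  age and SAPS-II; deaths receive a survival time uniform on (0, 28] days,
  survivors are censored at 28 days;
* urine output decreasing (hence fluid balance increasing) and AKI risk
  increasing with the exposure.

Crucially, the exposure entering the outcome draws is the normalized ECVP
load computed by :mod:`cvpload.metrics` on the *truncated, charted* series —
the estimand downstream stages measure is the one that generated the data,
so parameter-recovery experiments are exact by construction.

Identical :class:`~cvpload.config.SimConfig` (same seed included) yields a
bit-identical cohort and byte-identical CSV exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    CVPSeries,
    EmptySeriesError,
    PATIENT_COLUMNS,
    write_cvp_events,
    write_patients,
)
from .config import CohortConfig, SimConfig
from .metrics import compute_metrics
from .cohort import truncate_series

__all__ = ["SyntheticCohort", "generate_cohort", "export_cohort"]


@dataclass
class SyntheticCohort:
    """A generated cohort: series + patient table + generative truth.

    ``truth`` holds, per patient, the latent normalized ECVP load used in
    the outcome draws and the resulting event probabilities, so tests can
    re-evaluate the links exactly.
    """

    series: List[CVPSeries]
    patients: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def __post_init__(self) -> None:
        if len(self.series) != len(self.patients):
            raise ValueError("series and patient records must pair one-to-one")
        sid = sorted(s.patient_id for s in self.series)
        pid = sorted(self.patients["patient_id"])
        if sid != pid:
            raise ValueError("series and patient records must share patient ids")


def _sample_times(rng: np.random.Generator, start: float, end: float, cfg: SimConfig) -> np.ndarray:
    """Scheduled measurement times on [start, end] with per-point dropout."""
    span = end - start
    m = int(span / cfg.sampling_mean_interval_hr * 1.6) + 20
    offsets = np.concatenate(([0.0], np.cumsum(rng.exponential(cfg.sampling_mean_interval_hr, m))))
    while offsets[-1] < span:  # rare top-up for unlucky long gaps
        extra = np.cumsum(rng.exponential(cfg.sampling_mean_interval_hr, 20))
        offsets = np.concatenate((offsets, offsets[-1] + extra))
    t = start + offsets[offsets <= span]
    keep = rng.random(t.size) >= cfg.sampling_dropout_prob
    return t[keep]


def _ou_path(rng: np.random.Generator, times: np.ndarray, sd: float, tau: float) -> np.ndarray:
    """Exact Ornstein–Uhlenbeck bridge-free sampling at irregular times.

    x_{k+1} = a_k x_k + s_k z_k with a_k = exp(-dt_k/tau) and stationary
    variance sd^2. Evaluated blockwise via cumulative products so that long
    series avoid both the Python-loop cost and cumprod underflow.
    """
    n = times.size
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    if n == 1:
        return x
    loga = -np.diff(times) / tau
    s = sd * np.sqrt(-np.expm1(2.0 * loga))
    z = rng.normal(size=n - 1)
    i = 0
    while i < n - 1:
        cl = np.cumsum(loga[i:])
        j = i + int(np.searchsorted(-cl, 30.0))
        j = min(max(j, i + 1), n - 1)
        p = np.maximum(np.exp(cl[: j - i]), 1e-300)
        incr = np.cumsum(s[i:j] * z[i:j] / p)
        x[i + 1 : j + 1] = p * (x[i] + incr)
        i = j
    return x


def generate_cohort(
    cfg: SimConfig, cohort_cfg: CohortConfig | None = None
) -> SyntheticCohort:
    """Generate a seeded synthetic cohort under ``cfg``.

    ``cohort_cfg`` fixes the truncation window and ECVP threshold used to
    compute the latent exposure for the outcome links (defaults: 72 h,
    10 mmHg — the same defaults downstream analysis uses).
    """
    cohort_cfg = cohort_cfg or CohortConfig()
    rng = np.random.default_rng(int(cfg.seed))
    n = cfg.n_patients
    ids = np.arange(1, n + 1)

    # --- patient-level covariates (marginals near a septic ICU population) ---
    age = np.clip(np.round(rng.normal(66.0, 15.3, n)), 18, 99)
    female = (rng.random(n) < 0.42).astype(int)
    weight = np.round(np.clip(rng.normal(84.7, 25.0, n), 35, 250), 1)
    sofa = np.clip(np.round(rng.normal(9.1, 3.6, n)), 0, 24)
    sapsii = np.clip(np.round(rng.normal(51.6, 14.3, n)), 6, 120)
    chf = (rng.random(n) < 0.43).astype(int)
    liver_mild = (rng.random(n) < 0.26).astype(int)
    liver_severe = (rng.random(n) < 0.11).astype(int)
    renal = (rng.random(n) < 0.29).astype(int)
    diabetes = (rng.random(n) < 0.29).astype(int)
    cancer = (rng.random(n) < 0.12).astype(int)
    lactate_max = np.round(np.clip(rng.lognormal(math.log(3.3), 0.6, n), 0.4, 30), 1)
    creatinine_max = np.round(np.clip(rng.lognormal(math.log(1.8), 0.55, n), 0.2, 15), 1)
    hemoglobin_min = np.round(np.clip(rng.normal(9.3, 2.1, n), 3, 18), 1)
    platelet_min = np.clip(np.round(rng.normal(184.5, 132.2, n)), 5, 1000)
    inr_max = np.round(np.clip(rng.lognormal(math.log(1.8), 0.4, n), 0.8, 12), 1)
    map_min = np.clip(np.round(rng.normal(48.1, 14.4, n)), 20, 100)
    temp_mean = np.round(np.clip(rng.normal(36.9, 0.8, n), 32, 42), 1)
    spo2_min = np.clip(np.round(rng.normal(89.6, 9.4, n)), 40, 100)

    # --- CVP streams ---
    setpoint = rng.normal(cfg.cvp_setpoint_mean, cfg.cvp_setpoint_sd, n)
    start = rng.uniform(0.0, cfg.start_max_hr, n)
    end = rng.uniform(cfg.monitoring_end_lo_hr, cfg.monitoring_end_hi_hr, n)

    series: List[CVPSeries] = []
    norm_load = np.zeros(n)
    norm_defined = np.zeros(n, dtype=bool)
    for i in range(n):
        t = _sample_times(rng, start[i], end[i], cfg)
        if t.size == 0:  # every scheduled measurement dropped (vanishingly rare)
            continue
        x = _ou_path(rng, t, cfg.cvp_ou_sd, cfg.cvp_ou_tau_hr)
        v = np.round(np.maximum(setpoint[i] + x, 0.0), 1)
        s = CVPSeries(int(ids[i]), t, v)
        series.append(s)
        in_window = int((t <= cohort_cfg.window_hr).sum())
        if in_window >= 2:
            m = compute_metrics(
                truncate_series(s, cohort_cfg), cohort_cfg.ecvp_threshold_mmhg
            )
            norm_load[i] = m.normalized_ecvp_load_mmhg
            norm_defined[i] = m.norm_ecvp_defined

    # --- outcomes (drawn after all series so the link uses the pipeline's
    #     own exposure measure) ---
    p_death = expit(
        cfg.logit_intercept
        + cfg.beta_ecvp * norm_load
        + cfg.beta_age * age
        + cfg.beta_sapsii * sapsii
    )
    death = (rng.random(n) < p_death).astype(int)
    surv_draw = 28.0 * (1.0 - rng.random(n))  # uniform on (0, 28]
    # keep times strictly positive after rounding to 0.001 d resolution
    survival_days = np.maximum(
        np.round(np.where(death == 1, surv_draw, 28.0), 3), 0.001
    )

    urine = np.round(
        np.maximum(
            cfg.urine_base_ml
            + cfg.urine_slope_ml_per_mmhg * norm_load
            + rng.normal(0.0, cfg.urine_sd_ml, n),
            0.0,
        )
    )
    intake = np.round(rng.lognormal(math.log(cfg.intake_median_ml), cfg.intake_log_sd, n))
    p_aki = expit(cfg.aki_intercept + cfg.aki_beta * norm_load)
    aki = (rng.random(n) < p_aki).astype(int)

    have_series = np.isin(ids, [s.patient_id for s in series])
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "female": female,
            "weight": weight,
            "sofa": sofa,
            "sapsii": sapsii,
            "chf": chf,
            "liver_mild": liver_mild,
            "liver_severe": liver_severe,
            "renal": renal,
            "diabetes": diabetes,
            "cancer": cancer,
            "lactate_max": lactate_max,
            "creatinine_max": creatinine_max,
            "hemoglobin_min": hemoglobin_min,
            "platelet_min": platelet_min,
            "inr_max": inr_max,
            "map_min": map_min,
            "temp_mean": temp_mean,
            "spo2_min": spo2_min,
            "intake_72h_ml": intake,
            "urine_72h_ml": urine,
            "aki": aki,
            "death_28d": death,
            "survival_days": survival_days,
        },
        columns=PATIENT_COLUMNS,
    )[have_series].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "norm_ecvp_load": norm_load,
            "norm_ecvp_defined": norm_defined,
            "p_death": p_death,
            "p_aki": p_aki,
        }
    )[have_series].reset_index(drop=True)

    return SyntheticCohort(series=series, patients=patients, truth=truth, config=cfg)


def export_cohort(cohort: SyntheticCohort, directory: str | Path) -> Dict[str, Path]:
    """Write ``cvp_events.csv`` and ``patients.csv`` for pipeline ingest.

    Raises before writing anything if the cohort is empty; I/O failures
    propagate with the offending path.
    """
    if not cohort.series:
        raise EmptySeriesError("cannot export an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events = write_cvp_events(cohort.series, directory / "cvp_events.csv")
    patients = write_patients(cohort.patients, directory / "patients.csv")
    return {"events": events, "patients": patients}
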