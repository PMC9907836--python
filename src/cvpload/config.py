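"""Configuration objects for cohort selection and synthetic-cohort generation.

Two dataclasses govern the pipeline:

* :class:`CohortConfig` — the selection windows and the elevated-CVP
  threshold (defaults: 24 h latest monitoring start, 72 h analysis window,
  10 mmHg threshold, adult age cut-off, 0–50 mmHg artifact bounds).
* :class:`SimConfig` — generative parameters of the synthetic septic ICU
  cohort (sampling cadence, Ornstein–Uhlenbeck CVP dynamics, logistic
  outcome links, fluid/renal links).

Both validate on construction and raise :class:`ConfigError` naming the
offending field.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from typing import Any, Mapping, Optional

__all__ = [
    "ConfigError",
    "CohortConfig",
    "SimConfig",
    "calibrated_intercept",
    "REF_NORM_ECVP_MMHG",
    "REF_AGE_YEARS",
    "REF_SAPSII",
]


class ConfigError(ValueError):
    """A configuration field is missing or out of its valid range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# Reference covariate values used to anchor auto-calibrated logistic
# intercepts: a typical included patient (time-weighted elevated-CVP level,
# age in years, SAPS-II score).
REF_NORM_ECVP_MMHG = 14.3
REF_AGE_YEARS = 66.0
REF_SAPSII = 51.6


def calibrated_intercept(
    target_rate: float,
    beta_ecvp: float = 0.0,
    beta_age: float = 0.0,
    beta_sapsii: float = 0.0,
) -> float:
    """Logistic intercept giving ``target_rate`` at the reference covariates.

    Keeps the marginal event rate of a simulated cohort roughly constant when
    effect sizes change between experiments, so that power/calibration studies
    vary one thing at a time.
    """
    if not 0.0 < target_rate < 1.0:
        raise ConfigError("target_rate", "must be in (0, 1)")
    lp = (
        beta_ecvp * REF_NORM_ECVP_MMHG
        + beta_age * REF_AGE_YEARS
        + beta_sapsii * REF_SAPSII
    )
    return math.log(target_rate / (1.0 - target_rate)) - lp


@dataclass(frozen=True)
class CohortConfig:
    """Selection windows, elevated-CVP threshold and artifact bounds.

    Attributes
    ----------
    start_limit_hr:
        Latest admissible first CVP measurement (hours from ICU admission).
        Patients whose monitoring starts later are excluded.
    window_hr:
        Analysis window; only measurements at ``time <= window_hr`` are
        analysed, and monitoring must extend to at least this time.
    ecvp_threshold_mmhg:
        CVP level above which an inter-measurement segment counts as
        elevated (strict inequality on the segment's endpoint mean).
    min_age_years:
        Minimum age for inclusion.
    value_floor_mmhg / value_ceiling_mmhg:
        Artifact bounds; measurements outside are dropped before selection.
    median_split_tie:
        Where values equal to the median go in the high/low split
        ("low" or "high").
    """

    start_limit_hr: float = 24.0
    window_hr: float = 72.0
    ecvp_threshold_mmhg: float = 10.0
    min_age_years: float = 18.0
    value_floor_mmhg: float = 0.0
    value_ceiling_mmhg: float = 50.0
    median_split_tie: str = "low"

    def __post_init__(self) -> None:
        if not (0.0 < self.start_limit_hr < self.window_hr):
            raise ConfigError(
                "start_limit_hr",
                f"need 0 < start_limit_hr < window_hr, got "
                f"{self.start_limit_hr} vs window {self.window_hr}",
            )
        if self.ecvp_threshold_mmhg <= 0:
            raise ConfigError("ecvp_threshold_mmhg", "must be positive")
        if self.value_floor_mmhg >= self.value_ceiling_mmhg:
            raise ConfigError("value_floor_mmhg", "floor must be below ceiling")
        if self.min_age_years < 0:
            raise ConfigError("min_age_years", "must be non-negative")
        if self.median_split_tie not in ("low", "high"):
            raise ConfigError("median_split_tie", "must be 'low' or 'high'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "CohortConfig":
        return _from_mapping(cls, mapping)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic septic ICU cohort.

    CVP dynamics: each patient has a Gaussian setpoint
    ``N(cvp_setpoint_mean, cvp_setpoint_sd)`` plus a mean-reverting
    Ornstein–Uhlenbeck fluctuation (stationary sd ``cvp_ou_sd``, time
    constant ``cvp_ou_tau_hr``) sampled at irregular times: exponential
    gaps with mean ``sampling_mean_interval_hr``, each scheduled
    measurement independently dropped with ``sampling_dropout_prob``,
    from a start uniform on [0, ``start_max_hr``] to an end uniform on
    [``monitoring_end_lo_hr``, ``monitoring_end_hi_hr``].

    Outcome links (per-patient normalized elevated-CVP load ``L`` in mmHg,
    computed by the exposure-metrics layer on the truncated series):

    * 28-day death ~ Bernoulli(expit(beta0 + beta_ecvp*L + beta_age*age +
      beta_sapsii*sapsii)); deaths get a survival time uniform on (0, 28]
      days, survivors are censored at 28 days.
    * urine output over 72 h = urine_base_ml + urine_slope_ml_per_mmhg*L
      + Gaussian noise, floored at 0; intake is lognormal and independent
      of exposure, so fluid balance worsens with exposure through urine.
    * AKI ~ Bernoulli(expit(aki_beta0 + aki_beta*L)).

    ``beta0``/``aki_beta0`` default to None, meaning "auto-calibrate so the
    marginal rate at the reference covariates equals ``target_mortality`` /
    ``target_aki``" (see :func:`calibrated_intercept`).
    """

    n_patients: int
    seed: int = 0
    # sampling
    sampling_mean_interval_hr: float = 1.0
    sampling_dropout_prob: float = 0.15
    start_max_hr: float = 24.0
    monitoring_end_lo_hr: float = 72.0
    monitoring_end_hi_hr: float = 96.0
    # CVP dynamics
    cvp_setpoint_mean: float = 11.0
    cvp_setpoint_sd: float = 2.5
    cvp_ou_sd: float = 2.0
    cvp_ou_tau_hr: float = 6.0
    # mortality link (log-odds scale)
    beta0: Optional[float] = None
    beta_ecvp: float = math.log(1.058)
    beta_age: float = math.log(1.02)
    beta_sapsii: float = math.log(1.031)
    target_mortality: float = 0.398
    # fluid / renal links
    urine_base_ml: float = 7500.0
    urine_slope_ml_per_mmhg: float = -250.0
    urine_sd_ml: float = 1500.0
    intake_median_ml: float = 4000.0
    intake_log_sd: float = 0.55
    aki_beta0: Optional[float] = None
    aki_beta: float = 0.33
    target_aki: float = 0.877

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients", "must be >= 1")
        if int(self.seed) != self.seed:
            raise ConfigError("seed", "must be an integer")
        for name in (
            "sampling_mean_interval_hr",
            "cvp_setpoint_sd",
            "cvp_ou_sd",
            "cvp_ou_tau_hr",
            "urine_sd_ml",
            "intake_log_sd",
            "start_max_hr",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be positive")
        if not 0.0 <= self.sampling_dropout_prob <= 1.0:
            raise ConfigError("sampling_dropout_prob", "must be in [0, 1]")
        if not 0.0 < self.target_mortality < 1.0:
            raise ConfigError("target_mortality", "must be in (0, 1)")
        if not 0.0 < self.target_aki < 1.0:
            raise ConfigError("target_aki", "must be in (0, 1)")
        if self.monitoring_end_lo_hr > self.monitoring_end_hi_hr:
            raise ConfigError(
                "monitoring_end_lo_hr", "must be <= monitoring_end_hi_hr"
            )
        if self.monitoring_end_lo_hr <= self.start_max_hr:
            raise ConfigError(
                "monitoring_end_lo_hr", "monitoring must end after the latest start"
            )

    @property
    def logit_intercept(self) -> float:
        """Mortality-model intercept (auto-calibrated when beta0 is None)."""
        if self.beta0 is not None:
            return self.beta0
        return calibrated_intercept(
            self.target_mortality, self.beta_ecvp, self.beta_age, self.beta_sapsii
        )

    @property
    def aki_intercept(self) -> float:
        if self.aki_beta0 is not None:
            return self.aki_beta0
        return calibrated_intercept(self.target_aki, beta_ecvp=self.aki_beta)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SimConfig":
        return _from_mapping(cls, mapping)


def _from_mapping(cls, mapping: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ConfigError(unknown[0], f"unknown {cls.__name__} field")
    return cls(**dict(mapping))
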