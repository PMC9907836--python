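"""Config-driven orchestration: CSVs (or simulation) → tables, figures, log.

Stages: ingest → clean → select → truncate → metrics → stats → figures →
report. Every run writes a manifest with SHA-256 checksums of each artifact
and a run log echoing the seed, package versions, selection counts and all
convention-level settings (tie rules, boundaries, spans), so two runs with
the same config and seed are checksum-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CVPSeries,
    clean_values,
    read_cvp_events,
    read_patients,
    select_patients,
    truncate_series,
)
from .config import CohortConfig, SimConfig
from .metrics import compute_cohort_metrics
from .stats import (
    compare_groups,
    forward_logistic,
    km_logrank,
    lowess_mortality,
    median_split,
    quartile_duration_comparison,
    univariate_screen,
)
from .synthetic import export_cohort, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

#: variables for the baseline (admission-day) comparison table
TABLE1_VARS = [
    ("age", "continuous"), ("female", "binary"), ("weight", "continuous"),
    ("sofa", "continuous"), ("sapsii", "continuous"),
    ("chf", "binary"), ("liver_mild", "binary"), ("liver_severe", "binary"),
    ("renal", "binary"), ("diabetes", "binary"), ("cancer", "binary"),
    ("lactate_max", "continuous"), ("creatinine_max", "continuous"),
    ("hemoglobin_min", "continuous"), ("platelet_min", "continuous"),
    ("inr_max", "continuous"), ("map_min", "continuous"),
    ("temp_mean", "continuous"), ("spo2_min", "continuous"),
]

#: exposure metrics compared between survivors and non-survivors
TABLE2_VARS = [
    "cvp_duration_hr", "ecvp_duration_hr", "pct_ecvp_duration",
    "cvp_load", "ecvp_load", "norm_cvp_load", "norm_ecvp_load",
    "avg_ecvp_load",
]

#: candidates for the univariate mortality screen
SCREEN_VARS = [
    "age", "female", "sofa", "sapsii",
    "chf", "liver_mild", "liver_severe", "renal", "diabetes", "cancer",
    "lactate_max", "creatinine_max", "hemoglobin_min", "platelet_min",
    "inr_max", "map_min", "temp_mean", "spo2_min",
    "norm_ecvp_load",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: Exception, partial_manifest: dict):
        self.stage = stage
        self.cause = cause
        self.partial_manifest = partial_manifest
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Exactly one of ``sim`` (simulate a cohort) or ``events_path`` +
    ``patients_path`` (analyze user-supplied CSVs) must be provided.
    """

    out_dir: Path
    sim: Optional[SimConfig] = None
    events_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lowess_span: float = 0.8
    lowess_bin_width: float = 1.0
    screen_p: float = 0.20
    enter_p: float = 0.05
    make_figures: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        simulate = self.sim is not None
        supplied = self.events_path is not None and self.patients_path is not None
        if simulate == supplied:
            raise ValueError(
                "exactly one of a SimConfig or events+patients paths must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: Dict[str, Any] = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig.from_mapping(raw["sim"])
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig.from_mapping(raw["cohort"])
        for key in ("events_path", "patients_path"):
            if key in raw.get("inputs", {}):
                kwargs[key] = Path(raw["inputs"][key])
        for key in ("lowess_span", "lowess_bin_width", "screen_p", "enter_p", "make_figures"):
            if key in raw.get("stats", {}):
                kwargs[key] = raw["stats"][key]
        out = out_dir or raw.get("out_dir")
        if out is None:
            raise ValueError("an output directory is required (out_dir)")
        return cls(out_dir=Path(out), **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _comparison_table(df: pd.DataFrame, variables, group_col: str = "death_28d") -> pd.DataFrame:
    surv = df[df[group_col] == 0]
    non = df[df[group_col] == 1]
    rows = []
    for var, kind in variables:
        if var not in df.columns:
            continue
        a = surv[var].dropna()
        b = non[var].dropna()
        if a.empty or b.empty:
            continue
        r = compare_groups(a, b, variable=var, kind=kind)
        rows.append(
            {
                "variable": var,
                "test": r.test,
                "survivor": r.summary_a,
                "non_survivor": r.summary_b,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "note": r.note or "",
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; return the artifact manifest (also written).

    Raises :class:`PipelineError` naming the failing stage; artifacts written
    before the failure are listed in ``exc.partial_manifest``.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}
    run_log: Dict[str, Any] = {
        "package_version": __version__,
        "cohort_config": cfg.cohort.to_dict(),
        "lowess_span": cfg.lowess_span,
        "lowess_bin_width": cfg.lowess_bin_width,
        "screen_p": cfg.screen_p,
        "enter_p": cfg.enter_p,
        "conventions": {
            "window_boundary": "inclusive (time <= window_hr kept)",
            "ecvp_inequality": "strict (segment mean > threshold)",
            "ecvp_area": "full trapezoid area of elevated segments",
            "median_split_tie": cfg.cohort.median_split_tie,
            "quartile_boundary": "boundary values assigned to the lower quartile",
            "undefined_norm_ecvp": "recorded as 0 with norm_ecvp_defined=False, grouped low",
            "forward_entry": "likelihood-ratio p < enter_p",
        },
    }

    def record(path: Path) -> None:
        written[path.name] = _sha256(path)

    stage = "ingest"
    try:
        if cfg.sim is not None:
            cohort = generate_cohort(cfg.sim, cfg.cohort)
            paths = export_cohort(cohort, out)
            record(paths["events"])
            record(paths["patients"])
            series = cohort.series
            patients = cohort.patients
            run_log["seed"] = cfg.sim.seed
            run_log["sim_config"] = cfg.sim.to_dict()
        else:
            series = read_cvp_events(cfg.events_path)
            patients = read_patients(cfg.patients_path)
            run_log["inputs"] = {
                "events": str(cfg.events_path),
                "patients": str(cfg.patients_path),
            }

        stage = "clean"
        series = [clean_values(s, cfg.cohort) for s in series]

        stage = "select"
        series, patients, report = select_patients(series, patients, cfg.cohort)
        report.to_json(out / "selection_report.json")
        record(out / "selection_report.json")
        run_log["selection"] = {
            k: v for k, v in report.to_dict().items() if k != "reasons"
        }
        if report.n_included == 0:
            raise ValueError("no patients pass selection")

        stage = "truncate"
        series = [truncate_series(s, cfg.cohort) for s in series]

        stage = "metrics"
        metrics_df, failures = compute_cohort_metrics(series, cfg.cohort)
        metrics_df.to_csv(out / "exposure_metrics.csv", index=False)
        record(out / "exposure_metrics.csv")
        run_log["metrics_failures"] = {str(k): v for k, v in failures.items()}

        stage = "stats"
        data = metrics_df.merge(patients, on="patient_id", how="inner")
        data["fluid_balance_72h_ml"] = data["intake_72h_ml"] - data["urine_72h_ml"] \
            if {"intake_72h_ml", "urine_72h_ml"} <= set(data.columns) else np.nan

        table1 = _comparison_table(data, TABLE1_VARS)
        table1.to_csv(out / "table1.csv", index=False)
        record(out / "table1.csv")

        table2 = _comparison_table(data, [(v, "continuous") for v in TABLE2_VARS])
        table2.to_csv(out / "table2.csv", index=False)
        record(out / "table2.csv")

        split = median_split(data["norm_ecvp_load"], cfg.cohort.median_split_tie)
        data["high_norm_ecvp"] = split.high.to_numpy()
        run_log["median_split"] = {
            "threshold_mmhg": split.threshold,
            "n_high": split.n_high,
            "n_low": split.n_low,
        }

        km = km_logrank(
            data["survival_days"], data["death_28d"], data["high_norm_ecvp"]
        )
        km_payload = km.to_dict()
        km_payload["threshold_mmhg"] = split.threshold
        (out / "km.json").write_text(json.dumps(km_payload, indent=2))
        record(out / "km.json")

        low = lowess_mortality(
            data["norm_ecvp_load"],
            data["death_28d"],
            bin_width=cfg.lowess_bin_width,
            span=cfg.lowess_span,
        )
        low.to_frame().to_csv(out / "lowess.csv", index=False)
        record(out / "lowess.csv")
        run_log["lowess_empty_bins"] = low.empty_bins

        uni = univariate_screen(
            data, [v for v in SCREEN_VARS if v in data.columns],
            eligibility_p=cfg.screen_p,
        )
        eligible = [u.variable for u in uni if u.eligible]
        fwd = forward_logistic(data, eligible, p_enter=cfg.enter_p)
        t3_rows = []
        multi = fwd.table.set_index("variable") if len(fwd.table) else None
        for u in uni:
            row = {
                "variable": u.variable,
                "uni_odds_ratio": u.odds_ratio,
                "uni_ci_low": u.ci_low,
                "uni_ci_high": u.ci_high,
                "uni_p_value": u.p_value,
                "eligible": u.eligible,
                "flag": u.flag or "",
                "multi_odds_ratio": np.nan,
                "multi_ci_low": np.nan,
                "multi_ci_high": np.nan,
                "multi_p_value": np.nan,
            }
            if multi is not None and u.variable in multi.index:
                row["multi_odds_ratio"] = multi.loc[u.variable, "odds_ratio"]
                row["multi_ci_low"] = multi.loc[u.variable, "ci_low"]
                row["multi_ci_high"] = multi.loc[u.variable, "ci_high"]
                row["multi_p_value"] = multi.loc[u.variable, "p_value"]
            t3_rows.append(row)
        table3 = pd.DataFrame(t3_rows)
        table3.to_csv(out / "table3.csv", index=False)
        record(out / "table3.csv")
        run_log["forward_model"] = {"entered": fwd.entered, "notes": fwd.notes}

        quart = quartile_duration_comparison(data)
        loads = data["ecvp_load"].to_numpy(dtype=float)
        cuts = np.percentile(loads, [25, 50, 75])
        data["ecvp_load_quartile"] = (
            np.searchsorted(cuts, loads, side="left") + 1
        )
        pd.DataFrame([vars(qc) for qc in quart]).to_csv(
            out / "quartiles.csv", index=False
        )
        record(out / "quartiles.csv")

        data.to_csv(out / "analysis_dataset.csv", index=False)
        record(out / "analysis_dataset.csv")

        if cfg.make_figures:
            stage = "figures"
            from .figures import render_figures

            for p in render_figures(out):
                record(p)

        stage = "report"
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
        record(out / "run_log.json")
        manifest = {"files": dict(sorted(written.items()))}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError(stage, exc, {"files": dict(sorted(written.items()))}) from exc
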