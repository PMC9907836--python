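"""Figure rendering from pipeline artifacts.

Four standard views of a completed run:

* exposure–mortality bars with the lowess curve,
* Kaplan–Meier curves for the high/low exposure groups,
* fluid intake / urine output / balance by exposure group,
* elevated-duration comparison by survival status within load quartiles.

Figures are rebuilt from the CSV/JSON artifacts in a results directory, so
``cvpload report`` can regenerate them without re-running the analysis.
Missing inputs skip the corresponding figure with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["render_figures"]

logger = logging.getLogger(__name__)

_SAVE_OPTS = {"dpi": 150, "bbox_inches": "tight"}


def _fig_lowess(results: Path, out: Path) -> Path | None:
    src = results / "lowess.csv"
    if not src.exists():
        warnings.warn("lowess.csv missing; skipping dose-response figure")
        return None
    df = pd.read_csv(src)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(
        df["bin_mmhg"], 100 * df["raw_mortality"],
        width=0.85, color="#9ecae1", edgecolor="#3182bd", label="raw rate per bin",
    )
    ax.plot(
        df["bin_mmhg"], 100 * df["smoothed_mortality"],
        color="#de2d26", lw=2, label="lowess",
    )
    ax.set_xlabel("normalized ECVP load (mmHg)")
    ax.set_ylabel("28-day mortality (%)")
    ax.set_title("Mortality by normalized elevated-CVP load")
    ax.legend(frameon=False)
    path = out / "fig_lowess_mortality.png"
    fig.savefig(path, **_SAVE_OPTS)
    plt.close(fig)
    return path


def _fig_km(results: Path, out: Path) -> Path | None:
    src = results / "km.json"
    if not src.exists():
        warnings.warn("km.json missing; skipping survival figure")
        return None
    payload = json.loads(src.read_text())
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, style in (("low", "#3182bd"), ("high", "#de2d26")):
        curve = payload["curves"][label]
        ax.step(
            curve["times"], curve["survival"], where="post",
            color=style, lw=2, label=f"{label} normalized ECVP load",
        )
    ax.set_xlim(0, 28)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("days from ICU admission")
    ax.set_ylabel("survival probability")
    ax.set_title(
        f"28-day survival by exposure group (log-rank p = {payload['p_value']:.3g})"
    )
    ax.legend(frameon=False, loc="lower left")
    path = out / "fig_km_survival.png"
    fig.savefig(path, **_SAVE_OPTS)
    plt.close(fig)
    return path


def _fig_fluid(results: Path, out: Path) -> Path | None:
    src = results / "analysis_dataset.csv"
    if not src.exists():
        warnings.warn("analysis_dataset.csv missing; skipping fluid figure")
        return None
    df = pd.read_csv(src)
    needed = {"intake_72h_ml", "urine_72h_ml", "fluid_balance_72h_ml", "high_norm_ecvp"}
    if not needed <= set(df.columns):
        warnings.warn("fluid columns missing; skipping fluid figure")
        return None
    fig, ax = plt.subplots(figsize=(7, 4.5))
    variables = ["intake_72h_ml", "urine_72h_ml", "fluid_balance_72h_ml"]
    labels = ["intake", "urine output", "fluid balance"]
    width = 0.35
    xs = np.arange(len(variables))
    for offset, (grp, color, name) in enumerate(
        ((False, "#3182bd", "low"), (True, "#de2d26", "high"))
    ):
        sub = df[df["high_norm_ecvp"] == grp]
        med = [sub[v].median() for v in variables]
        q1 = [np.percentile(sub[v], 25) for v in variables]
        q3 = [np.percentile(sub[v], 75) for v in variables]
        err = [np.subtract(med, q1), np.subtract(q3, med)]
        ax.bar(
            xs + (offset - 0.5) * width, med, width,
            yerr=err, capsize=3, color=color, label=f"{name} load", alpha=0.85,
        )
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs, labels)
    ax.set_ylabel("72-h volume (mL), median with IQR")
    ax.set_title("Fluid status by normalized ECVP load group")
    ax.legend(frameon=False)
    path = out / "fig_fluid_balance.png"
    fig.savefig(path, **_SAVE_OPTS)
    plt.close(fig)
    return path


def _fig_quartiles(results: Path, out: Path) -> Path | None:
    src = results / "analysis_dataset.csv"
    if not src.exists():
        warnings.warn("analysis_dataset.csv missing; skipping quartile figure")
        return None
    df = pd.read_csv(src)
    needed = {"ecvp_load_quartile", "pct_ecvp_duration", "death_28d"}
    if not needed <= set(df.columns):
        warnings.warn("quartile columns missing; skipping quartile figure")
        return None
    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = 0.35
    xs = np.arange(4)
    for offset, (death, color, name) in enumerate(
        ((0, "#3182bd", "survivor"), (1, "#de2d26", "non-survivor"))
    ):
        med, lo, hi = [], [], []
        for q in range(1, 5):
            vals = df[(df["ecvp_load_quartile"] == q) & (df["death_28d"] == death)][
                "pct_ecvp_duration"
            ]
            if vals.empty:
                med.append(0.0), lo.append(0.0), hi.append(0.0)
            else:
                m = vals.median()
                med.append(m)
                lo.append(m - np.percentile(vals, 25))
                hi.append(np.percentile(vals, 75) - m)
        ax.bar(
            xs + (offset - 0.5) * width, med, width,
            yerr=[lo, hi], capsize=3, color=color, label=name, alpha=0.85,
        )
    ax.set_xticks(xs, [f"Q{q}" for q in range(1, 5)])
    ax.set_xlabel("ECVP load quartile")
    ax.set_ylabel("% ECVP duration of CVP duration, median with IQR")
    ax.set_title("Elevated-CVP duration by outcome within load quartiles")
    ax.legend(frameon=False)
    path = out / "fig_quartile_duration.png"
    fig.savefig(path, **_SAVE_OPTS)
    plt.close(fig)
    return path


def render_figures(results_dir: str | Path, out_dir: str | Path | None = None) -> List[Path]:
    """Render all four figures from a results directory; return written paths."""
    results = Path(results_dir)
    out = Path(out_dir) if out_dir is not None else results
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fn in (_fig_lowess, _fig_km, _fig_fluid, _fig_quartiles):
        p = fn(results, out)
        if p is not None:
            paths.append(p)
    return paths
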