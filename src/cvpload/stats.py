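"""Statistical battery linking exposure metrics to 28-day mortality.

Descriptive group comparisons (t / Wilcoxon rank-sum / chi-square, chosen by
variable type and a Lilliefors-corrected normality check), the crude
dose–response curve (lowess on per-patient binary outcomes with raw rates
per integer exposure bin), median-split Kaplan–Meier + log-rank survival
comparison, quartile-stratified duration comparisons, and the univariate
screen (p < 0.20) feeding a forward stepwise logistic model (likelihood-
ratio entry at p < 0.05, Wald CIs for the odds ratios).

Conventions worth knowing:

* Normality is declared at p >= 0.05 on the Lilliefors-corrected
  Kolmogorov–Smirnov test (estimated mean/sd make the plain KS test
  anticonservative).
* The median split sends values equal to the median to the LOW group by
  default; patients with an undefined normalized ECVP load carry value 0
  and therefore land low (no elevation = minimal exposure).
* Quartile boundaries belong to the lower quartile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "MedianSplit",
    "KMResult",
    "LowessResult",
    "UnivariateResult",
    "ForwardLogisticResult",
    "QuartileComparison",
    "assess_normality",
    "compare_groups",
    "median_split",
    "km_logrank",
    "lowess_mortality",
    "univariate_screen",
    "forward_logistic",
    "quartile_duration_comparison",
]


# ---------------------------------------------------------------------------
# normality and two-group comparisons


@dataclass(frozen=True)
class NormalityResult:
    p_value: float
    normal: bool
    note: Optional[str] = None


def assess_normality(x: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Lilliefors-corrected KS test against a fitted normal.

    Samples below 8 observations or with zero spread default to non-normal
    with an explanatory note.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        return NormalityResult(p_value=0.0, normal=False, note="small_sample")
    if np.std(x) == 0.0:
        return NormalityResult(p_value=0.0, normal=False, note="degenerate_sd")
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return NormalityResult(p_value=float(p), normal=bool(p >= alpha))


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # "t" | "wilcoxon" | "chisq"
    summary_a: str
    summary_b: str
    statistic: float
    p_value: float
    note: Optional[str] = None


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def _count_pct(x: np.ndarray) -> str:
    k = int(np.sum(x == 1))
    return f"{k} ({100.0 * k / x.size:.1f})"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    variable: str = "",
    kind: str = "continuous",
) -> ComparisonResult:
    """Compare a variable between two groups, choosing the test as appropriate.

    Continuous variables normal in both groups use Student's t (mean ± sd
    summaries); otherwise the Wilcoxon rank-sum test (median [IQR]).
    Binary/categorical variables use the Pearson chi-square on the 2×k
    contingency table, without continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"{variable}: both groups must be non-empty")

    if kind in ("binary", "categorical"):
        levels = np.union1d(np.unique(a), np.unique(b))
        table = np.array(
            [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]]
        )
        # degenerate tables (a level absent in both groups cannot occur by
        # construction; a single shared level means no variation at all)
        if table.shape[1] < 2:
            return ComparisonResult(
                variable, "chisq", _count_pct(a), _count_pct(b),
                statistic=0.0, p_value=1.0, note="degenerate_table",
            )
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return ComparisonResult(
            variable, "chisq", _count_pct(a), _count_pct(b),
            statistic=float(stat), p_value=float(p),
        )

    note = None
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        normal = False
        note = "zero_variance_wilcoxon_fallback"
    else:
        normal = assess_normality(a).normal and assess_normality(b).normal
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            variable, "t", _mean_sd(a), _mean_sd(b),
            statistic=float(stat), p_value=float(p),
        )
    if np.array_equal(np.unique(a), np.unique(b)) and np.unique(a).size == 1:
        # identical constants in both groups: no evidence of difference
        return ComparisonResult(
            variable, "wilcoxon", _median_iqr(a), _median_iqr(b),
            statistic=0.0, p_value=1.0, note="degenerate_constant",
        )
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        variable, "wilcoxon", _median_iqr(a), _median_iqr(b),
        statistic=float(stat), p_value=float(p), note=note,
    )


# ---------------------------------------------------------------------------
# median split and survival


@dataclass(frozen=True)
class MedianSplit:
    threshold: float
    high: pd.Series  # boolean, aligned with the input index
    n_high: int
    n_low: int
    tie_rule: str


def median_split(values: pd.Series, tie_rule: str = "low") -> MedianSplit:
    """Dichotomize at the sample median; ties go to ``tie_rule`` group."""
    v = pd.Series(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 patients")
    threshold = float(np.median(v))
    if v.nunique() == 1:
        raise ValueError("all values identical: median split impossible")
    high = v > threshold if tie_rule == "low" else v >= threshold
    return MedianSplit(
        threshold=threshold,
        high=high,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        tie_rule=tie_rule,
    )


@dataclass
class KMResult:
    curves: Dict[str, dict]  # label -> {"times", "survival", "at_risk"}
    statistic: float
    p_value: float
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "curves": self.curves,
            "logrank_statistic": self.statistic,
            "p_value": self.p_value,
            "note": self.note,
        }


def km_logrank(
    durations: Sequence[float],
    events: Sequence[int],
    high: Sequence[bool],
    labels: Tuple[str, str] = ("low", "high"),
) -> KMResult:
    """Product-limit curves per group and the two-group log-rank test.

    With zero events overall the curves are flat at 1.0 and the test is
    undefined; a p-value of 1.0 is returned with a note.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    high = np.asarray(high, dtype=bool)
    if durations.min() <= 0:
        raise ValueError("survival times must be positive")
    curves: Dict[str, dict] = {}
    for label, mask in zip(labels, (~high, high)):
        if mask.sum() == 0:
            raise ValueError(f"group '{label}' has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(durations[mask], events[mask], label=label)
        sf = kmf.survival_function_
        curves[label] = {
            "times": [float(t) for t in sf.index],
            "survival": [float(v) for v in sf[label]],
            "at_risk": [int(v) for v in kmf.event_table["at_risk"]],
        }
    if events.sum() == 0:
        return KMResult(curves, statistic=0.0, p_value=1.0, note="no_events")
    res = logrank_test(
        durations[~high], durations[high], events[~high], events[high]
    )
    return KMResult(
        curves, statistic=float(res.test_statistic), p_value=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# lowess dose-response


@dataclass
class LowessResult:
    bin_centers: np.ndarray
    raw_rates: np.ndarray
    bin_counts: np.ndarray
    smoothed: np.ndarray
    empty_bins: List[float]
    span: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_mmhg": self.bin_centers,
                "n_patients": self.bin_counts,
                "raw_mortality": self.raw_rates,
                "smoothed_mortality": self.smoothed,
            }
        )


def lowess_mortality(
    norm_load: Sequence[float],
    death: Sequence[int],
    bin_width: float = 1.0,
    span: float = 0.8,
    min_bins: int = 5,
) -> LowessResult:
    """Crude exposure–mortality relationship.

    Patients are binned by their exposure rounded to the nearest multiple of
    ``bin_width`` (raw per-bin mortality, bar-plot style); the smooth curve
    is an unweighted lowess fit through the per-patient (exposure, death)
    points, evaluated at the bin centers. Bins inside the observed range
    with no patients are reported in ``empty_bins``.
    """
    x = np.asarray(norm_load, dtype=float)
    y = np.asarray(death, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("exposure and outcome must be equal-length, non-empty")
    binned = np.round(x / bin_width) * bin_width
    centers_all = np.arange(
        binned.min(), binned.max() + 0.5 * bin_width, bin_width
    )
    counts = np.array([(binned == c).sum() for c in centers_all])
    nonempty = counts > 0
    if nonempty.sum() < min_bins:
        raise ValueError(
            f"only {int(nonempty.sum())} non-empty bins (< {min_bins}); "
            "consider a wider bin_width"
        )
    centers = centers_all[nonempty]
    rates = np.array([y[binned == c].mean() for c in centers])
    fit = sm_lowess(y, x, frac=span, it=0)
    smoothed = np.interp(centers, fit[:, 0], fit[:, 1])
    return LowessResult(
        bin_centers=centers,
        raw_rates=rates,
        bin_counts=counts[nonempty],
        smoothed=smoothed,
        empty_bins=[float(c) for c in centers_all[~nonempty]],
        span=span,
    )


# ---------------------------------------------------------------------------
# logistic regression: univariate screen + forward selection


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    eligible: bool
    flag: Optional[str] = None  # "separation" | "constant" | "fit_failed"


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Logit fit returning (result, flag); flags separation/non-convergence."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, warn_convergence=False)
        except PerfectSeparationError:
            return None, "separation"
        except Exception:
            separated = any(
                isinstance(w.message, PerfectSeparationWarning) for w in caught
            )
            return None, "separation" if separated else "fit_failed"
        if any(isinstance(w.message, PerfectSeparationWarning) for w in caught):
            return res, "separation"
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not res.mle_retvals.get("converged", False):
        return res, "separation"
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        return res, "separation"
    if np.any(np.abs(params[1:]) > 15) or np.any(bse > 100):
        return res, "separation"
    return res, None


def univariate_screen(
    df: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "death_28d",
    eligibility_p: float = 0.20,
) -> List[UnivariateResult]:
    """One single-predictor logistic fit per candidate.

    Candidates with p below ``eligibility_p`` are flagged eligible for the
    multivariate step; constant predictors and separated fits are excluded
    with an explanatory flag.
    """
    y = df[outcome].to_numpy(dtype=float)
    out: List[UnivariateResult] = []
    for var in candidates:
        x = df[[var]].astype(float)
        if x[var].nunique() < 2:
            out.append(
                UnivariateResult(var, np.nan, np.nan, np.nan, np.nan, False, "constant")
            )
            continue
        res, flag = _fit_logit(y, x)
        if flag is not None:
            out.append(UnivariateResult(var, np.nan, np.nan, np.nan, np.nan, False, flag))
            continue
        beta = float(res.params.iloc[1])
        lo, hi = res.conf_int().iloc[1]
        p = float(res.pvalues.iloc[1])
        out.append(
            UnivariateResult(
                var,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
                p_value=p,
                eligible=bool(p < eligibility_p),
            )
        )
    return out


@dataclass
class ForwardLogisticResult:
    entered: List[str]
    table: pd.DataFrame  # variable, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    notes: List[str] = field(default_factory=list)


def forward_logistic(
    df: pd.DataFrame,
    eligible: Sequence[str],
    outcome: str = "death_28d",
    p_enter: float = 0.05,
) -> ForwardLogisticResult:
    """Forward stepwise logistic regression by likelihood-ratio entry.

    Starting from the intercept-only model, the candidate whose addition has
    the smallest likelihood-ratio p-value is entered while that p-value is
    below ``p_enter``. The final model reports odds ratios with Wald 95%
    confidence intervals. Collinear duplicates add no likelihood and are
    never entered. With fewer than ~10 observations per candidate a warning
    note is attached.
    """
    eligible = list(dict.fromkeys(eligible))  # dedupe, keep order
    notes: List[str] = []
    y = df[outcome].to_numpy(dtype=float)
    if not eligible:
        return ForwardLogisticResult(
            entered=[],
            table=pd.DataFrame(
                columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"]
            ),
            converged=True,
            notes=["no eligible variables"],
        )
    if len(df) <= 10 * len(eligible):
        notes.append(
            f"n={len(df)} is small for {len(eligible)} candidates (10 per variable advised)"
        )

    null_res = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
    ll_current = float(null_res.llf)
    entered: List[str] = []
    remaining = list(eligible)
    last_res = None

    while remaining:
        best = None
        for var in remaining:
            res, flag = _fit_logit(y, df[entered + [var]].astype(float))
            if flag is not None:
                continue
            lr = 2.0 * (float(res.llf) - ll_current)
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[1]:
                best = (var, p, res)
        if best is None or best[1] >= p_enter:
            break
        var, _, res = best
        entered.append(var)
        remaining.remove(var)
        ll_current = float(res.llf)
        last_res = res

    if not entered:
        return ForwardLogisticResult(
            entered=[],
            table=pd.DataFrame(
                columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"]
            ),
            converged=True,
            notes=notes + ["no variable met the entry criterion"],
        )

    res = last_res
    ci = res.conf_int()
    rows = []
    for var in entered:
        rows.append(
            {
                "variable": var,
                "odds_ratio": float(np.exp(res.params[var])),
                "ci_low": float(np.exp(ci.loc[var, 0])),
                "ci_high": float(np.exp(ci.loc[var, 1])),
                "p_value": float(res.pvalues[var]),
            }
        )
    return ForwardLogisticResult(
        entered=entered,
        table=pd.DataFrame(rows),
        converged=bool(res.mle_retvals.get("converged", False)),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# quartile-stratified duration comparison


@dataclass(frozen=True)
class QuartileComparison:
    quartile: int  # 1..4
    n: int
    n_survivor: int
    n_nonsurvivor: int
    p_duration: float
    p_pct_duration: float
    skipped: bool
    note: Optional[str] = None


def quartile_duration_comparison(df: pd.DataFrame) -> List[QuartileComparison]:
    """Within ECVP-load quartiles, compare durations by survival status.

    Quartiles are cut at the 25/50/75th percentiles of ``ecvp_load``,
    boundary values assigned to the lower quartile. Within each quartile the
    elevated-CVP duration and its percentage of total monitoring time are
    compared between survivors and non-survivors by the Wilcoxon rank-sum
    test. Quartiles containing a single outcome class are skipped with a
    note.
    """
    required = {"ecvp_load", "ecvp_duration_hr", "pct_ecvp_duration", "death_28d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    loads = df["ecvp_load"].to_numpy(dtype=float)
    cuts = np.percentile(loads, [25, 50, 75])
    # boundary values fall in the lower quartile (searchsorted 'left')
    q = np.searchsorted(cuts, loads, side="left")
    out: List[QuartileComparison] = []
    for k in range(4):
        sub = df[q == k]
        surv = sub[sub["death_28d"] == 0]
        non = sub[sub["death_28d"] == 1]
        if len(surv) == 0 or len(non) == 0 or len(sub) < 2:
            out.append(
                QuartileComparison(
                    quartile=k + 1, n=len(sub),
                    n_survivor=len(surv), n_nonsurvivor=len(non),
                    p_duration=np.nan, p_pct_duration=np.nan,
                    skipped=True, note="single outcome class",
                )
            )
            continue
        _, p_dur = sps.mannwhitneyu(
            surv["ecvp_duration_hr"], non["ecvp_duration_hr"], alternative="two-sided"
        )
        _, p_pct = sps.mannwhitneyu(
            surv["pct_ecvp_duration"], non["pct_ecvp_duration"], alternative="two-sided"
        )
        out.append(
            QuartileComparison(
                quartile=k + 1, n=len(sub),
                n_survivor=len(surv), n_nonsurvivor=len(non),
                p_duration=float(p_dur), p_pct_duration=float(p_pct),
                skipped=False,
            )
        )
    return out
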