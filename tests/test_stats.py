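"""Statistical battery: test choice, splits, survival, lowess, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cvpload import (
    assess_normality,
    compare_groups,
    forward_logistic,
    km_logrank,
    lowess_mortality,
    median_split,
    quartile_duration_comparison,
    univariate_screen,
)

from oracles import pearson_chi2_2x2


# --- normality ---------------------------------------------------------------


def test_normality_verdicts():
    rng = np.random.default_rng(7)
    assert assess_normality(rng.normal(0, 1, 500)).normal
    assert not assess_normality(rng.exponential(1.0, 500)).normal
    constant = assess_normality(np.full(100, 3.0))
    assert not constant.normal and constant.note == "degenerate_sd"
    small = assess_normality([1.0, 2.0, 3.0])
    assert not small.normal and small.note == "small_sample"


# --- two-group comparisons ---------------------------------------------------


def test_chi_square_agrees_with_hand_pearson():
    """AKI-style 2x2: 511/550 vs 429/521 events; exact Pearson agreement."""
    a = np.concatenate([np.ones(511), np.zeros(39)])
    b = np.concatenate([np.ones(429), np.zeros(92)])
    r = compare_groups(a, b, "aki", kind="binary")
    expected_stat = pearson_chi2_2x2(511, 39, 429, 92)
    assert r.test == "chisq"
    assert r.statistic == pytest.approx(expected_stat, abs=1e-9)
    assert r.p_value < 0.001
    assert r.p_value == pytest.approx(sps.chi2.sf(expected_stat, 1), abs=1e-12)


def test_identical_balanced_binary_groups_give_p_one():
    g = np.concatenate([np.ones(50), np.zeros(50)])
    r = compare_groups(g, g.copy(), "flag", kind="binary")
    assert r.p_value == pytest.approx(1.0)


def test_large_shift_detected_by_t_and_wilcoxon():
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, 200)
    b = a + 10.0
    rt = compare_groups(a, b, "x")
    assert rt.test == "t" and rt.p_value < 1e-10
    skew_a = rng.exponential(1, 200)
    rw = compare_groups(skew_a, skew_a + 10.0, "x")
    assert rw.test == "wilcoxon" and rw.p_value < 1e-10


def test_zero_variance_falls_back_to_wilcoxon():
    rng = np.random.default_rng(3)
    r = compare_groups(np.full(50, 5.0), rng.normal(9, 1, 50), "x")
    assert r.test == "wilcoxon"
    assert r.note == "zero_variance_wilcoxon_fallback"


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        compare_groups([], [1.0, 2.0], "x")


# --- median split ------------------------------------------------------------


def test_median_split_basic():
    s = median_split(pd.Series([1.0, 2.0, 3.0, 4.0]))
    assert s.threshold == 2.5
    assert list(s.high) == [False, False, True, True]
    assert s.n_high == 2 and s.n_low == 2


def test_median_split_tie_rule():
    values = pd.Series([1.0, 2.0, 2.0, 3.0])
    low_rule = median_split(values, tie_rule="low")
    assert low_rule.threshold == 2.0
    assert low_rule.n_high == 1  # only the 3 goes high; ties stay low
    high_rule = median_split(values, tie_rule="high")
    assert high_rule.n_high == 3  # ties join the high group

    with pytest.raises(ValueError, match="identical"):
        median_split(pd.Series([2.0, 2.0, 2.0]))


# --- survival ----------------------------------------------------------------


def test_km_no_events_flat_curves():
    r = km_logrank([28.0] * 20, [0] * 20, [False] * 10 + [True] * 10)
    assert r.p_value == 1.0 and r.note == "no_events"
    assert all(v == 1.0 for c in r.curves.values() for v in c["survival"])


def test_km_maximal_separation():
    durations = [1.0] * 30 + [28.0] * 30
    events = [1] * 30 + [0] * 30
    high = [True] * 30 + [False] * 30
    r = km_logrank(durations, events, high)
    assert r.p_value < 1e-10
    assert r.curves["high"]["survival"][-1] == 0.0
    assert r.curves["low"]["survival"][-1] == 1.0


def test_km_at_28_equals_one_minus_mortality(small_cohort):
    """Censoring only at day 28 makes KM(28) = 1 - observed mortality exactly."""
    p = small_cohort.patients
    half = np.arange(len(p)) < len(p) // 2
    r = km_logrank(p["survival_days"], p["death_28d"], half)
    for label, mask in (("low", ~half), ("high", half)):
        km28 = r.curves[label]["survival"][-1]
        assert km28 == pytest.approx(
            1.0 - p[mask]["death_28d"].mean(), abs=1e-12
        )


def test_km_empty_group_is_error():
    with pytest.raises(ValueError, match="zero subjects"):
        km_logrank([5.0, 6.0], [1, 0], [True, True])


# --- lowess ------------------------------------------------------------------


def test_lowess_flat_under_null():
    rng = np.random.default_rng(21)
    load = rng.uniform(10, 22, 4000)
    death = (rng.random(4000) < 0.4).astype(int)
    r = lowess_mortality(load, death)
    assert np.all(np.abs(r.smoothed - death.mean()) < 0.02)


def test_lowess_monotone_under_linear_link():
    rng = np.random.default_rng(22)
    load = rng.uniform(10, 22, 6000)
    death = (rng.random(6000) < (load - 8.0) / 20.0).astype(int)
    r = lowess_mortality(load, death)
    rho = sps.spearmanr(r.bin_centers, r.smoothed).statistic
    assert rho > 0.95


def test_lowess_too_few_bins_errors():
    with pytest.raises(ValueError, match="bin"):
        lowess_mortality(np.full(100, 12.0), np.zeros(100))


def test_lowess_reports_empty_bins():
    load = np.concatenate([np.full(30, 10.0), np.full(30, 11.0), np.full(30, 12.0),
                           np.full(30, 13.0), np.full(30, 16.0)])
    death = np.zeros(150)
    r = lowess_mortality(load, death)
    assert {14.0, 15.0} <= set(r.empty_bins)


# --- logistic regression -----------------------------------------------------


def _binary_frame(rng, n=500):
    x = rng.normal(0, 1, n)
    y = (rng.random(n) < 0.4).astype(int)
    return pd.DataFrame({"x": x, "death_28d": y})


def test_univariate_separation_and_constant_flags():
    rng = np.random.default_rng(31)
    df = _binary_frame(rng)
    df["perfect"] = df["death_28d"].astype(float)
    df["const"] = 1.0
    res = {r.variable: r for r in univariate_screen(df, ["x", "perfect", "const"])}
    assert res["perfect"].flag == "separation" and not res["perfect"].eligible
    assert res["const"].flag == "constant" and not res["const"].eligible
    assert res["x"].flag is None
    assert res["x"].ci_low <= res["x"].odds_ratio <= res["x"].ci_high


def test_univariate_screen_calibration_under_null():
    """A pure-noise predictor passes the p<0.20 screen in ~20% of replicates."""
    rng = np.random.default_rng(32)
    eligible = 0
    reps = 200
    for _ in range(reps):
        df = _binary_frame(rng, n=1000)
        (r,) = univariate_screen(df, ["x"])
        eligible += r.eligible
    assert 0.15 <= eligible / reps <= 0.25


def test_forward_selects_true_predictor_among_noise():
    rng = np.random.default_rng(33)
    hits = 0
    reps = 50
    for _ in range(reps):
        n = 2000
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, (n, 5))
        p = 1.0 / (1.0 + np.exp(-(-0.4 + np.log(2.0) * x)))
        df = pd.DataFrame(noise, columns=[f"z{i}" for i in range(5)])
        df["x"] = x
        df["death_28d"] = (rng.random(n) < p).astype(int)
        uni = univariate_screen(df, ["x"] + [f"z{i}" for i in range(5)])
        eligible = [r.variable for r in uni if r.eligible]
        fwd = forward_logistic(df, eligible)
        hits += "x" in fwd.entered
    assert hits / reps >= 0.95


def test_forward_empty_and_collinear_cases():
    rng = np.random.default_rng(34)
    n = 1500
    x = rng.normal(0, 1, n)
    p = 1.0 / (1.0 + np.exp(-(np.log(3.0) * x)))
    df = pd.DataFrame({"x": x, "x_copy": x, "death_28d": (rng.random(n) < p).astype(int)})

    empty = forward_logistic(df, [])
    assert empty.entered == [] and "no eligible" in empty.notes[0]

    fwd = forward_logistic(df, ["x", "x_copy"])
    assert len(fwd.entered) == 1  # the duplicate adds no likelihood
    assert fwd.table["ci_low"].iloc[0] <= fwd.table["odds_ratio"].iloc[0] <= fwd.table["ci_high"].iloc[0]


# --- quartile comparison -----------------------------------------------------


def _quartile_frame(rng, n=400):
    return pd.DataFrame(
        {
            "ecvp_load": rng.uniform(0, 900, n),
            "ecvp_duration_hr": rng.uniform(0, 70, n),
            "pct_ecvp_duration": rng.uniform(0, 100, n),
            "death_28d": (rng.random(n) < 0.4).astype(int),
        }
    )


def test_quartile_assignment_order_invariant():
    rng = np.random.default_rng(41)
    df = _quartile_frame(rng)
    res_a = quartile_duration_comparison(df)
    res_b = quartile_duration_comparison(df.sample(frac=1.0, random_state=1))
    assert [(q.quartile, q.n, q.p_duration) for q in res_a] == [
        (q.quartile, q.n, q.p_duration) for q in res_b
    ]
    assert sum(q.n for q in res_a) == len(df)


def test_quartile_single_class_skipped():
    rng = np.random.default_rng(42)
    df = _quartile_frame(rng, n=8)
    df["death_28d"] = (df["ecvp_load"] > np.median(df["ecvp_load"])).astype(int)
    res = quartile_duration_comparison(df)
    assert any(q.skipped for q in res)
    for q in res:
        if q.skipped:
            assert np.isnan(q.p_duration)


def test_quartile_boundary_goes_low():
    df = pd.DataFrame(
        {
            "ecvp_load": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            "ecvp_duration_hr": np.arange(8.0),
            "pct_ecvp_duration": np.arange(8.0),
            "death_28d": [0, 1] * 4,
        }
    )
    res = quartile_duration_comparison(df)
    # 25th percentile = 1.75, 50th = 3.5, 75th = 5.25; the value at a cut
    # belongs to the lower quartile
    assert [q.n for q in res] == [2, 2, 2, 2]
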