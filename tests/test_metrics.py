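"""Exposure-calculus tests: hand oracles, segment rules, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvpload import CVPSeries, CohortConfig, build_segments, compute_cohort_metrics, compute_metrics
from cvpload.metrics import DegenerateSeriesError

from oracles import fine_grid_load, naive_exposure


# --- segment classification -------------------------------------------------


def test_boundary_mean_is_not_elevated(make_series):
    """A segment whose endpoint mean sits exactly at the threshold is not ECVP."""
    segs = build_segments(make_series([0, 2], [8, 12]), threshold=10.0)
    assert len(segs) == 1
    assert segs[0].mean_cvp == 10.0
    assert not segs[0].is_ecvp


def test_constant_at_threshold_has_no_elevated_segments(make_series):
    s = make_series(np.arange(0, 73, 3.0), np.full(25, 10.0))
    assert not any(seg.is_ecvp for seg in build_segments(s))
    m = compute_metrics(s)
    assert m.ecvp_duration_hr == 0.0 and not m.norm_ecvp_defined


def test_segments_match_hand_oracle(make_series):
    s = make_series([0, 1, 3], [12, 14, 8])
    segs = build_segments(s)
    expected = naive_exposure(s.times, s.values)["segments"]
    assert [(g.mean_cvp, g.is_ecvp, g.area) for g in segs] == expected
    assert [(g.mean_cvp, g.is_ecvp, g.area) for g in segs] == [
        (13.0, True, 13.0),
        (11.0, True, 22.0),
    ]


# --- hand-worked metric examples --------------------------------------------


@pytest.mark.parametrize(
    "times, values, expected",
    [
        (
            [0, 1, 3],
            [12, 14, 8],
            dict(
                cvp_load=35.0, cvp_duration=3.0, ecvp_load=35.0, ecvp_duration=3.0,
                norm_ecvp=35.0 / 3.0, pct=100.0,
            ),
        ),
        (
            [0, 1, 2, 3],
            [12, 14, 4, 4],
            dict(
                cvp_load=26.0, cvp_duration=3.0, ecvp_load=13.0, ecvp_duration=1.0,
                norm_ecvp=13.0, avg_ecvp=13.0 / 3.0, pct=100.0 / 3.0,
            ),
        ),
    ],
)
def test_hand_worked_examples(make_series, times, values, expected):
    s = make_series(times, values)
    m = compute_metrics(s)
    oracle = naive_exposure(times, values)
    # first against the independent loop oracle …
    assert m.cvp_load_mmhg_hr == pytest.approx(oracle["cvp_load"], rel=1e-12)
    assert m.ecvp_load_mmhg_hr == pytest.approx(oracle["ecvp_load"], rel=1e-12)
    assert m.ecvp_duration_hr == pytest.approx(oracle["ecvp_duration_hr"], rel=1e-12)
    # … then against the frozen hand numbers
    assert m.cvp_load_mmhg_hr == pytest.approx(expected["cvp_load"])
    assert m.cvp_duration_hr == pytest.approx(expected["cvp_duration"])
    assert m.ecvp_load_mmhg_hr == pytest.approx(expected["ecvp_load"])
    assert m.ecvp_duration_hr == pytest.approx(expected["ecvp_duration"])
    assert m.normalized_ecvp_load_mmhg == pytest.approx(expected["norm_ecvp"])
    assert m.pct_ecvp_duration == pytest.approx(expected["pct"])
    if "avg_ecvp" in expected:
        assert m.averaged_ecvp_load_mmhg == pytest.approx(expected["avg_ecvp"])


def test_constant_subthreshold_series(make_series):
    s = make_series(np.arange(0.0, 73.0, 1.0), np.full(73, 8.0))
    m = compute_metrics(s)
    assert m.normalized_cvp_load_mmhg == pytest.approx(8.0)
    assert m.ecvp_load_mmhg_hr == 0.0
    assert m.normalized_ecvp_load_mmhg == 0.0
    assert not m.norm_ecvp_defined


def test_single_measurement_is_degenerate(make_series):
    with pytest.raises(DegenerateSeriesError, match="patient 7"):
        compute_metrics(make_series([5.0], [12.0], patient_id=7))


# --- property tests ----------------------------------------------------------


@st.composite
def cvp_series(draw):
    n = draw(st.integers(min_value=2, max_value=40))
    gaps = draw(
        st.lists(st.floats(0.01, 5.0, allow_nan=False), min_size=n - 1, max_size=n - 1)
    )
    start = draw(st.floats(0.0, 24.0, allow_nan=False))
    values = draw(st.lists(st.floats(0.0, 40.0, allow_nan=False), min_size=n, max_size=n))
    times = start + np.concatenate(([0.0], np.cumsum(gaps)))
    return CVPSeries(1, times, np.asarray(values))


@settings(max_examples=60, derandomize=True)
@given(cvp_series())
def test_load_matches_fine_grid_and_oracle(s):
    m = compute_metrics(s)
    ref = fine_grid_load(s.times, s.values, n_grid=2001)
    if ref > 0:
        assert abs(m.cvp_load_mmhg_hr - ref) / ref < 1e-9
    oracle = naive_exposure(s.times, s.values)
    assert m.ecvp_load_mmhg_hr == pytest.approx(oracle["ecvp_load"], rel=1e-12, abs=1e-12)
    assert m.ecvp_duration_hr == pytest.approx(oracle["ecvp_duration_hr"], rel=1e-12, abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(cvp_series())
def test_metric_invariants(s):
    m = compute_metrics(s)
    assert 0.0 <= m.ecvp_duration_hr <= m.cvp_duration_hr + 1e-12
    assert 0.0 <= m.ecvp_load_mmhg_hr <= m.cvp_load_mmhg_hr + 1e-9
    assert 0.0 <= m.pct_ecvp_duration <= 100.0 + 1e-9
    assert m.averaged_ecvp_load_mmhg <= m.normalized_cvp_load_mmhg + 1e-9
    assert m.normalized_ecvp_load_mmhg >= m.averaged_ecvp_load_mmhg - 1e-9
    if m.norm_ecvp_defined:
        assert m.normalized_ecvp_load_mmhg > 10.0


@settings(max_examples=40, derandomize=True)
@given(cvp_series(), st.floats(0.0, 40.0))
def test_threshold_monotonicity(s, higher):
    """Raising the threshold can only shrink elevated load and duration."""
    lo = compute_metrics(s, threshold=10.0)
    hi = compute_metrics(s, threshold=10.0 + abs(higher))
    assert hi.ecvp_load_mmhg_hr <= lo.ecvp_load_mmhg_hr + 1e-9
    assert hi.ecvp_duration_hr <= lo.ecvp_duration_hr + 1e-12


@settings(max_examples=40, derandomize=True)
@given(cvp_series(), st.floats(0.1, 100.0))
def test_time_shift_and_scaling(s, shift):
    base = compute_metrics(s)
    shifted = compute_metrics(CVPSeries(1, s.times + shift, s.values))
    assert shifted.cvp_load_mmhg_hr == pytest.approx(base.cvp_load_mmhg_hr, rel=1e-9, abs=1e-9)
    assert shifted.ecvp_duration_hr == pytest.approx(base.ecvp_duration_hr, rel=1e-9, abs=1e-9)

    k = 2.5
    scaled = compute_metrics(CVPSeries(1, s.times * k, s.values))
    assert scaled.cvp_load_mmhg_hr == pytest.approx(k * base.cvp_load_mmhg_hr, rel=1e-9, abs=1e-9)
    assert scaled.ecvp_duration_hr == pytest.approx(k * base.ecvp_duration_hr, rel=1e-9, abs=1e-12)
    assert scaled.normalized_cvp_load_mmhg == pytest.approx(
        base.normalized_cvp_load_mmhg, rel=1e-9
    )
    if base.norm_ecvp_defined:
        assert scaled.normalized_ecvp_load_mmhg == pytest.approx(
            base.normalized_ecvp_load_mmhg, rel=1e-9
        )


# --- cohort-level table -----------------------------------------------------


def test_cohort_metrics_order_invariance_and_failures(make_series):
    good1 = make_series([0, 10, 72], [12, 9, 11], patient_id=3)
    good2 = make_series([1, 30, 71], [8, 8, 8], patient_id=1)
    degenerate = make_series([5.0], [12.0], patient_id=2)
    df_a, fail_a = compute_cohort_metrics([good1, good2, degenerate], CohortConfig())
    df_b, fail_b = compute_cohort_metrics([degenerate, good2, good1], CohortConfig())
    assert list(df_a["patient_id"]) == [1, 3]
    assert df_a.equals(df_b)
    assert set(fail_a) == set(fail_b) == {2}
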