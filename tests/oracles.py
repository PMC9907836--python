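"""Hand-coded reference implementations, deliberately naive.

These stay independent of the package internals: plain Python loops and
textbook formulas, used to pin down expected values for the exposure
calculus and the chi-square statistic.
"""

from __future__ import annotations

import numpy as np


def naive_exposure(times, values, threshold=10.0):
    """Loop-based trapezoid exposure metrics for one series."""
    times = list(map(float, times))
    values = list(map(float, values))
    assert len(times) == len(values) >= 2
    cvp_load = 0.0
    ecvp_load = 0.0
    ecvp_duration = 0.0
    segments = []
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        mean = (values[i] + values[i + 1]) / 2.0
        area = mean * dt
        elevated = mean > threshold
        segments.append((mean, elevated, area))
        cvp_load += area
        if elevated:
            ecvp_load += area
            ecvp_duration += dt
    cvp_duration = times[-1] - times[0]
    return {
        "segments": segments,
        "cvp_duration_hr": cvp_duration,
        "ecvp_duration_hr": ecvp_duration,
        "cvp_load": cvp_load,
        "ecvp_load": ecvp_load,
        "norm_cvp_load": cvp_load / cvp_duration,
        "norm_ecvp_load": (ecvp_load / ecvp_duration) if ecvp_duration > 0 else 0.0,
        "avg_ecvp_load": ecvp_load / cvp_duration,
        "pct_ecvp_duration": 100.0 * ecvp_duration / cvp_duration,
    }


def fine_grid_load(times, values, n_grid=20001):
    """Numerically integrate the piecewise-linear interpolant on a dense grid."""
    times = np.asarray(times, dtype=float)
    grid = np.union1d(np.linspace(times[0], times[-1], n_grid), times)
    return float(np.trapezoid(np.interp(grid, times, values), grid))


def pearson_chi2_2x2(a1, a0, b1, b0):
    """Textbook Pearson chi-square on a 2x2 table of counts."""
    obs = np.array([[a1, a0], [b1, b0]], dtype=float)
    total = obs.sum()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows @ cols / total
    return float(((obs - exp) ** 2 / exp).sum())
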