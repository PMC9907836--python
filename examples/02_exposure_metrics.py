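"""Compute trapezoidal CVP exposure metrics for a hand-made series.

A patient measured at 0, 1, 2 and 3 hours with CVP 12, 14, 4, 4 mmHg:
the first segment (mean 13 mmHg) is elevated (> 10 mmHg), the others are
not, so the elevated load is the first trapezoid only.
"""

import numpy as np

from cvpload import CVPSeries, build_segments, compute_metrics

series = CVPSeries(
    patient_id=1,
    times=np.array([0.0, 1.0, 2.0, 3.0]),
    values=np.array([12.0, 14.0, 4.0, 4.0]),
)

print("segments (mean mmHg, elevated?, area mmHg*hr):")
for seg in build_segments(series, threshold=10.0):
    print(f"  [{seg.t_start:.0f}-{seg.t_end:.0f} h] mean {seg.mean_cvp:4.1f}  "
          f"elevated={seg.is_ecvp!s:5}  area {seg.area:.1f}")

m = compute_metrics(series, threshold=10.0)
print(f"\nCVP load:              {m.cvp_load_mmhg_hr:.1f} mmHg*hr over {m.cvp_duration_hr:.0f} h")
print(f"ECVP load:             {m.ecvp_load_mmhg_hr:.1f} mmHg*hr over {m.ecvp_duration_hr:.0f} h elevated")
print(f"normalized CVP load:   {m.normalized_cvp_load_mmhg:.2f} mmHg (time-weighted mean CVP)")
print(f"normalized ECVP load:  {m.normalized_ecvp_load_mmhg:.2f} mmHg (time-weighted mean while elevated)")
print(f"averaged ECVP load:    {m.averaged_ecvp_load_mmhg:.2f} mmHg (elevated area over the whole stay)")
print(f"% time elevated:       {m.pct_ecvp_duration:.1f} %")
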