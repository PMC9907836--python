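# cvpload

Time-weighted central venous pressure (CVP) exposure analysis for septic ICU
cohorts: trapezoidal load/duration metrics on irregularly sampled CVP streams,
cohort selection, and the survival/regression battery linking elevated-CVP
exposure to 28-day mortality — with a seeded synthetic-cohort generator so the
whole chain can be developed and validated without credentialed clinical data.

## The problem and who this is for

In sepsis, persistently elevated CVP marks venous congestion and poor fluid
tolerance, but "elevated CVP exposure" has two dimensions — how *high* and for
how *long*. Because ICU charting is irregular (CVP is not logged on a fixed
cadence), a plain average of charted values misrepresents the true exposure.
This package is aimed at critical-care researchers who want time-weighted
exposure metrics and the standard downstream epidemiology, reproducibly, from
long-format measurement CSVs.

## The exposure calculus

For a patient with CVP values `v_1..v_N` at hours `t_1 < … < t_N` (truncated
to the first 72 h of the ICU stay), the piecewise-linear curve is decomposed
into segments; segment *i* has trapezoid area `(v_i + v_{i+1})/2 · (t_{i+1} −
t_i)` and is **elevated** (ECVP) when its endpoint-mean exceeds 10 mmHg
(strict inequality). Then:

- **CVP load** = Σ all segment areas (mmHg·hr); **CVP duration** = `t_N − t_1`
- **ECVP load** = Σ elevated segment areas; **ECVP duration** = Σ elevated
  segment lengths
- **normalized CVP/ECVP load** = load / its own duration — a time-weighted
  average pressure (mmHg); the normalized ECVP load is the mean CVP *while
  elevated*, so it isolates the magnitude dimension
- **averaged ECVP load** = ECVP load / CVP duration — dilutes elevated
  exposure over the whole monitored period
- **% ECVP duration** = 100 · ECVP duration / CVP duration — the duration
  dimension

The statistical battery splits the cohort at the median normalized ECVP load
(Kaplan–Meier + log-rank), draws the crude dose–response curve (per-mmHg-bin
mortality with a lowess smooth), compares elevated durations between
survivors and non-survivors within ECVP-load quartiles, and builds a
forward-stepwise logistic model for 28-day death from a univariate screen
(screen at p < 0.20, likelihood-ratio entry at p < 0.05, Wald CIs).

## Worked example

```python
import numpy as np
from cvpload import CVPSeries, compute_metrics

s = CVPSeries(1, times=np.array([0., 1., 2., 3.]),
                 values=np.array([12., 14., 4., 4.]))
m = compute_metrics(s, threshold=10.0)
```

This prints (see `examples/02_exposure_metrics.py`):

```
CVP load:              26.0 mmHg*hr over 3 h
ECVP load:             13.0 mmHg*hr over 1 h elevated
normalized CVP load:   8.67 mmHg (time-weighted mean CVP)
normalized ECVP load:  13.00 mmHg (time-weighted mean while elevated)
averaged ECVP load:    4.33 mmHg (elevated area over the whole stay)
% time elevated:       33.3 %
```

Only the first hour (segment mean 13 mmHg) is elevated, so the elevated load
is that single 13 mmHg·hr trapezoid; normalized by its 1 h duration it says
"while elevated, this patient averaged 13 mmHg".

On a full synthetic cohort (`examples/03_survival_and_regression.py`, 1000
patients, seed 7) the pipeline prints:

```
included patients: 949, 28-day mortality 37.1%
median normalized ECVP load: 11.87 mmHg (high n=474, low n=475)
log-rank p = 0.0124  (KM at 28 d: low 0.667, high 0.591)
forward stepwise model (likelihood-ratio entry at p < 0.05):
      variable  odds_ratio  ci_low  ci_high  p_value
        sapsii       1.029   1.019    1.039    0.000
norm_ecvp_load       1.074   1.029    1.122    0.001
           age       1.012   1.003    1.022    0.013
```

i.e. the high-exposure half of the cohort survives less, and the forward
model recovers exactly the three variables that generate mortality in the
simulator (severity score, exposure, age), with the exposure odds ratio per
mmHg close to its generative value.

## Command line

```bash
cvpload simulate --n 500 --seed 7 --out data/           # synthetic CSVs
cvpload analyze --events data/cvp_events.csv \
                --patients data/patients.csv --out results/
cvpload report --results results/                        # re-render figures
```

`analyze` accepts any long-format `cvp_events.csv` (`patient_id,time_hr,
cvp_mmhg`) plus a `patients.csv` with at least `patient_id,age,death_28d,
survival_days`; a YAML config can override every window, threshold and
convention (see `cvpload analyze --help`).

## Layout

- `src/cvpload/` — library (`config`, `cohort`, `metrics`, `synthetic`,
  `stats`, `pipeline`, `figures`, `validation`, `cli`)
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite with hand-coded oracles and simulation experiments
- `docs/methods.md` — model, conventions, numerical choices and limitations
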