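# Methods

This note documents the models, conventions and numerical choices behind
`cvpload`: what is computed, which decisions were genuinely open, and what
passing the test suite does and does not establish.

## Exposure model

CVP exposure is quantified on the piecewise-linear interpolant of the charted
values. Each inter-measurement interval is one *segment*; its area is the
trapezoid `(v_i + v_{i+1})/2 · Δt` and it is classified elevated when its
endpoint-mean CVP is **strictly** above the threshold (default 10 mmHg, the
level conventionally regarded as potentially harmful venous congestion). Three
conventions deserve emphasis:

1. **Full-area, not excess-area.** The elevated load is the whole trapezoid
   area of elevated segments, not the area above the threshold line. The
   normalized ECVP load is therefore the time-weighted mean CVP *during*
   elevated intervals (a pressure on the familiar 10–20 mmHg scale, always
   above the threshold when defined), rather than a mean exceedance, which
   would live near 1–4 mmHg and be much harder to interpret clinically.
2. **Whole-segment classification.** A segment whose endpoints straddle the
   threshold is classified wholly by its endpoint mean; no interpolated
   crossing point is introduced. This keeps the decomposition exact
   (elevated + non-elevated areas sum to the total load by construction) and
   matches how charted intervals are read clinically.
3. **No elevation ⇒ exposure 0, flagged.** A patient whose segments never
   exceed the threshold has an undefined normalized ECVP load; it is recorded
   as 0 with `norm_ecvp_defined = False`. Zero preserves the exposure
   ordering (no elevation = minimal exposure) and the flag keeps the choice
   auditable; the median split sends these patients to the low-exposure
   group, consistent with that reading.

CVP duration is `t_N − t_1` (first to last measurement), not time from ICU
admission; the normalized loads are therefore insensitive to when monitoring
happened to start, which is the point of normalizing.

## Cohort selection

Patients enter the analysis when a CVP series exists, the first measurement
falls within 24 h of ICU admission, monitoring extends to at least 72 h
(judged on the untruncated stream — otherwise the criterion would be vacuous
once truncation caps every series at 72 h), and age is ≥ 18 years. Analysis
then uses measurements with `time ≤ 72 h`, boundary inclusive, without
interpolating at the cut. Exclusion reasons are assigned with fixed
precedence (no CVP → age → late start → early end) so flowchart counts are
deterministic. Values outside 0–50 mmHg are treated as charting artifacts and
dropped before selection; both bounds are configurable and echoed in the run
log.

## Statistical battery

- **Normality**: Lilliefors-corrected Kolmogorov–Smirnov at α = 0.05 (the
  plain KS test with estimated mean/sd is anticonservative). Continuous
  variables normal in both groups are compared by Student's t (mean ± sd),
  otherwise Wilcoxon rank-sum (median [IQR]); categorical variables by
  Pearson chi-square without continuity correction.
- **Median split**: at the sample median of normalized ECVP load; values
  equal to the median go low by default (configurable). Survival is compared
  by Kaplan–Meier curves and the two-group log-rank test on (0, 28] days with
  censoring at 28.
- **Dose–response**: patients are binned at 1 mmHg resolution (nearest
  integer) for raw per-bin mortality; the smooth curve is an unweighted
  lowess (span 0.8, no robustifying iterations — with a binary response the
  residual-based reweighting of robust lowess is meaningless) through the
  per-patient (exposure, death) points, evaluated at the bin centers. Empty
  interior bins are reported.
- **Regression**: a univariate logistic screen flags candidates at p < 0.20;
  forward selection then adds, from the eligible set, the variable with the
  smallest likelihood-ratio p-value while that p-value is below 0.05. The
  0.20/0.05 split reads the screening gate and the entry criterion as
  separate thresholds — the final model then contains only terms significant
  at conventional levels. Odds-ratio confidence intervals are Wald intervals
  on the log scale. Perfect separation, constant predictors and failed fits
  are flagged and excluded rather than entered.
- **Quartile analysis**: ECVP load quartiles are cut at the 25/50/75th
  percentiles with boundary values assigned to the lower quartile; within
  each quartile, elevated duration and its percentage of monitoring time are
  compared between survivors and non-survivors by Wilcoxon rank-sum,
  skipping quartiles with a single outcome class.

## Synthetic cohort

The generator emulates the data-generating structure the analysis assumes:

- **Sampling**: monitoring starts uniform on [0, 24] h and ends uniform on
  [72, 96] h; scheduled times follow exponential gaps (mean 1 h) and each
  scheduled measurement is independently dropped with probability 0.15. The
  resulting streams produce realistic late-start/early-end exclusions.
- **CVP dynamics**: per-patient setpoint `N(11, 2.5²)` mmHg plus a
  discretized Ornstein–Uhlenbeck fluctuation (stationary sd 2 mmHg, time
  constant 6 h) evaluated exactly at the irregular times, floored at 0 and
  charted at 0.1 mmHg resolution. OU was chosen because it is the simplest
  autocorrelated mean-reverting process; the autocorrelation makes elevated
  episodes temporally clustered, which the duration analysis needs.
- **Outcomes**: 28-day death is Bernoulli with logit =
  `β₀ + β_ecvp·L + β_age·age + β_sapsii·sapsii`, where `L` is the normalized
  ECVP load computed by the package's own metric layer on the truncated,
  charted series — so the estimand downstream fits is exactly the quantity
  that generated the outcome, and parameter recovery is a clean test of the
  pipeline rather than of a latent-vs-measured gap. Default effect sizes are
  OR 1.058/mmHg (exposure), 1.02/year, 1.031/point. Deaths get a survival
  time uniform on (0, 28]; survivors are censored at 28 d (the analysis uses
  only 28-day status plus KM, so any monotone survival-time model would do;
  uniform is the simplest sufficient choice).
- **Intercept calibration**: `β₀` defaults to the value that yields the
  target marginal mortality (39.8%) at reference covariates (exposure
  14.3 mmHg, age 66, SAPS-II 51.6). This is a fixed experiment-design rule:
  when an experiment changes an effect size, the event rate — and hence the
  Fisher information — stays comparable instead of saturating. The AKI
  intercept is calibrated the same way (target 87.7%).
- **Fluids/renal**: 72-h urine = 7500 − 250·L mL + noise (floored at 0);
  intake is lognormal (median 4000 mL) and deliberately independent of
  exposure, so fluid balance worsens with exposure through urine output
  only; AKI risk rises at 0.33 log-odds/mmHg.

What the generator does **not** emulate: informative sampling (sicker
patients charted more often), measurement error beyond rounding, competing
risks and ICU discharge before 72 h, correlated covariates (age, severity and
comorbidities are drawn independently of the exposure), missing covariates,
or any raw event-table structure. Passing tests therefore show that the
pipeline measures what it claims on data satisfying its own assumptions —
not that those assumptions hold in any particular clinical database.

## Validation experiments and problem sizes

`cvpload.validation` packages four experiments (used by the test suite and
`scripts/acceptance.py`); per-replicate seeds derive from one base seed via
`SeedSequence` spawning:

- **Trapezoid oracle**: 1000 random irregular series; the segment calculus
  agrees with dense-grid integration of the interpolant to ~4·10⁻¹⁶ relative
  error, and the elevated/non-elevated decomposition is exact (residual 0).
- **Parameter recovery**: 200 cohorts × 1000 patients at a true exposure OR
  of 1.5/mmHg; the mean refitted OR lands within 5% of truth with ~95% Wald
  CI coverage.
- **Null calibration**: 200 cohorts × 600 patients at a zero exposure
  effect; the univariate test rejects at ~4–5%, inside its nominal band.
  600 patients gives ~150 per quartile, comparable to a mid-sized cohort.
- **Log-rank power**: 50 cohorts × 2000 patients at a true OR of 1.2/mmHg;
  the median-split log-rank test rejects in ~100% of replicates.

One joint null requirement is knowingly not met and intentionally left
failing: demanding that *all four* within-quartile duration comparisons
exceed p = 0.05 in ≥ 90% of null replicates. Four independent tests that each
hold their nominal 5% level jointly pass with probability ≈ 0.95⁴ ≈ 0.81
(measured: 0.845 with per-test rejection 0.044), so that joint bound is
achievable only by a mis-calibrated, conservative test. The suite asserts
both facts — nominal per-test level (passes) and the joint bound (fails) —
rather than degrading the test to satisfy the bound.

## Numerical and implementation notes

- The OU path is sampled exactly at the irregular times via the closed-form
  transition `x' = e^{−Δt/τ} x + sd·√(1−e^{−2Δt/τ})·z`, vectorized blockwise
  with cumulative products capped at e⁻³⁰ decay per block to avoid underflow
  while keeping full precision.
- The total load is accumulated as elevated + non-elevated partial sums so
  the decomposition identity holds exactly in floating point.
- Degenerate inputs: single-measurement series raise a typed error naming
  the patient at the metric layer and are reported-and-skipped at cohort
  level; constant samples are declared non-normal with a degenerate-sd note;
  an all-identical exposure column makes the median split an error rather
  than an arbitrary partition.
- Determinism: one `numpy` Generator per cohort, a fixed draw order
  (covariates, then per-patient series, then outcomes), CSV exports via
  shortest-round-trip float formatting, and figure rendering on the Agg
  backend; two runs with identical config and seed produce checksum-identical
  artifact manifests.

## Limitations

The package treats severity scores, comorbidities and labs as given
covariates (it does not compute SOFA/SAPS-II from raw physiology, phenotype
sepsis, or read raw ICU event tables), performs complete-case analysis, and
fits no survival regression beyond KM/log-rank (no Cox model, no competing
risks, no propensity adjustment). Exposure metrics depend on charting
density through the interpolation assumption: long gaps are bridged
linearly, which can smooth over excursions between measurements.
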