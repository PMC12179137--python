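# Methods

## Model

A subject's day is split by two times: wake time `t1` and bedtime `t2`
(decimal hours after midnight). Blood pressure rises exponentially from
a nocturnal baseline `base` toward a plateau `base + incr` during the
wake phase, and decays back toward `base` after bedtime at the same
rate `k`:

- wake, `t1 ≤ t < min(t2, 24)`: `base + incr (1 − e^{−k(t−t1)})`
- post-bed, `t2 ≤ t < 24`: the bedtime value decays as `e^{−k(t−t2)}`
- pre-wake, `t < t1`: the decay continues with elapsed time
  `τ = max(t + 24 − t2, 0)`

The model is asymmetric (unlike cosinor fits), continuous at bedtime and
at midnight, and bounded in `[base, base + incr]`. It is generally
*discontinuous at `t1`*: unless `k·(t1 + 24 − t2)` is large the
overnight decay has not reached `base` when the wake-phase rise restarts
there. This is a property of the functional form itself and has a
practical consequence for fitting (below).

Two conventions are ours to fix because the strict inequalities of the
phase definitions leave the boundaries open: phases are half-open
(`pre_wake = [0, t1)`, `wake = [t1, min(t2, 24))`, `post_bed = [t2, 24)`),
with closures chosen so each branch meets its neighbour continuously.
When `t2 > 24` (bedtime past midnight, allowed up to 25 h) the post-bed
branch is unreachable within the day and the pre-wake exponent is
clamped at zero (`τ ≥ 0`), which keeps predictions inside
`[base, base + incr]`. Days run midnight-to-midnight on local wall-clock
time; daylight-saving jumps are not handled.

The extended variant reassigns the pre-wake sleep segment to the
previous physiological day: its pre-wake branch uses the previous day's
fitted `base` and `incr` (the current day's `k`, `t1`, `t2` are kept).
Per-day fitting forces one more convention: the basic model's pre-wake
branch reuses the *same* day's `t2` as a stand-in for the previous
night's bedtime.

## Fitting

Each subject-day-channel is fitted independently — there is deliberately
no pooling or hierarchical adjustment across subjects, so estimates for
one subject never depend on who else is in the dataset. The objective is
unweighted least squares, minimised by `scipy.optimize.least_squares`
(trust-region reflective) inside the box
`base ∈ [80, 200]` (systolic) / `[20, 120]` (diastolic), `incr ∈ [0, 60]`,
`k ∈ [0.01, 2]` /h, `t1 ∈ [1, 11]` h, `t2 ∈ [18, 25]` h, with
`ftol = xtol = gtol = 1e-10` and an iteration cap of 200 (mapped to a
function-evaluation budget of 1200 for the 2-point Jacobian). Starting
values are the day's minimum pressure (`base`), its max–min spread
(`incr`), and `k = 0.3`, `t1 = 5`, `t2 = 22`, clipped into the box.

Because the objective is discontinuous in `t1` wherever a data point
crosses the wake boundary, a single gradient start can stall in the
wrong inter-observation interval. The fitter therefore also evaluates a
deterministic variable-projection grid — for each node of a coarse `k`
and `t2` grid crossed with a fine (0.25 h) `t1` grid, `base` and `incr`
are solved in closed form and clipped — and polishes the best nodes at
up to five distinct `t1` values with the same bounded solver, keeping
the lowest-SSE solution (the prescribed start wins ties). On noise-free
dense days this recovers the generating parameters essentially exactly,
and it agrees with an exhaustive grid search of the whole box in the
test suite.

Days with fewer than 6 observations (parameters + 1) are skipped and
flagged, never fitted. In the extended variant the carry for day `d` is
the most recent previously *fitted* day's `(base, incr)`; a day with no
fitted predecessor is fitted as basic, which ties its pre-wake segment
to its own estimates. Non-convergence returns the best iterate flagged
`converged = False`. Repeated timestamps are kept as repeated residual
terms. Fitting contains no randomness: reruns are bitwise identical.

## Diagnostics and variability

Weighted residuals are `100 · (observed − predicted) / observed` (%),
with the observed-minus-predicted sign convention; for a well-specified
fit they scatter about zero with no time trend. Per subject, the
day-level estimates are summarised by median and (min, max) range, and
intra-individual variability by the coefficient of variation of `base`
and `incr` across days (sample sd, `n − 1` denominator; at least two
fitted days required). Inter-individual variability pools *day-level*
estimates across all subjects before computing the CV — this matches the
observation that the overall CV exceeds every per-subject CV, which a
CV-of-subject-medians would not reproduce. Skipped days are excluded
everywhere.

## Synthetic cohorts

The generator emulates the study design the model was built for: 6
subjects × 14 days, daily observation counts Poisson with mean 32,
observation times uniform over the day, and Gaussian measurement noise
(sd 5 mmHg systolic, 4 diastolic) around the basic-model curve of
day-specific true parameters. Subject-level parameters are drawn from
truncated normals inside the fitting bounds (systolic means
`base 104, incr 16, k 0.33, t1 4.8, t2 23.0`, matching the pooled
medians reported for healthy young adults on this device class;
diastolic analogues scaled down). Dispersion values are not published,
so they were calibrated to the features the source cohort does report:
between-subject sds (8 mmHg base, 4 mmHg incr, 0.15 /h k, 1.2 h t1,
1.0 h t2) exceed the day-to-day within-subject sds (4 mmHg base,
5 mmHg incr, applied to base and incr only), subject draws are
truncated at mean ± 2 sd, and subject-level `base` and `incr` are
negatively correlated (ρ = −0.5) — in the real cohort high-baseline
subjects show smaller rises, compressing daytime plateaus into a narrow
band (roughly 104–126 mmHg) while baselines span ~82–112 mmHg. With
these defaults ≳ 98% of simulated systolic values fall in the observed
74–140 mmHg window, intra-individual base CVs land around 3–8% versus a
pooled CV of 6–10%, and incr CVs are several times larger — the
qualitative pattern seen in real monitors. A diastolic draw at or above
its systolic partner is resampled.

What the generator does *not* emulate: activity- and posture-driven
transients, heteroscedastic or non-Gaussian device error, the monitor's
actual (proprietary) trigger schedule, missing nights (the uniform
schedule always samples the trough), and any base/incr autocorrelation
across days. Passing recovery tests on these cohorts therefore shows
the estimator works when the model is correctly specified and the night
is observed; it does not certify performance on real wear-pattern data.

## Numerical and design notes

- Time is converted as `hour + minute/60 + second/3600`; `day_index`
  counts calendar days since the subject's first date.
- Starting values landing on a bound are nudged `1e-8` of the box width
  inside so the trust-region solver starts strictly feasible.
- A flat day (`incr → 0`) leaves `k`, `t1`, `t2` unidentified; the fit
  returns `incr` at its lower bound with `base` near the day mean, and
  such days simply contribute their `base`/`incr` to summaries.
- Subjects whose bedtime is near or past midnight have weakly identified
  baselines (the trough is never observed within the day); their
  day-level `base` estimates carry several mmHg of extra variance. This
  is intrinsic to per-day fitting of late sleepers, not a solver issue.
- Measurement CSVs are written at 0.01 mmHg precision; fit tables round
  `base`/`incr` to 1 decimal and `k`/`t1`/`t2` to 2, matching how such
  estimates are conventionally reported.
- Test problem sizes (cohort subsets, 48–96 points per noise-free day,
  20 seeds for the variability-pattern check) were chosen so the whole
  suite runs in a few minutes on one core while keeping each check
  statistically meaningful.

## Known limitations

- The model has no covariates (age, BMI, activity) and no shared
  information across subjects or days beyond the extended carry.
- `k` is shared between the morning rise and the evening decay; real
  profiles may rise and fall at different rates.
- The wake-boundary discontinuity means predictions just before `t1` can
  sit several mmHg above `base` for slow decayers; profile plots render
  this faithfully.
- Extended-variant carries are fixed constants from the previous day's
  fit, not co-estimated, so uncertainty is not propagated along the
  chain.
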