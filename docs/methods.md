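# Methods

## Model and estimation

A child's reading scale score is treated as piecewise linear in calendar
time with three segment rates — kindergarten (`β1`), summer vacation
(`β2`), 1st grade (`β3`) — and an intercept `β0` at the date of the
first assessment. Exposures are whole days computed with half-open
`[start, end)` intervals from a `SegmentCalendar`; this convention is
leap-year aware and reproduces the 2020 spans used in the projections
(1 Jan → 16 Mar = 75 days, 16 Mar → 1 Sep = 169, total 244).

Estimation is ordinary least squares in closed form. The contract is
`β̂ = (X'X)⁻¹X'y`; the implementation solves the least-squares problem by
a stable decomposition (`numpy.linalg.lstsq`) and forms `(X'X)⁻¹` only
for the covariance. Errors are assumed independent Gaussian per
assessment record. No cluster-robust or within-child correlation
adjustment is applied: replicating the original independent-error
analysis is the point, and the synthetic generator produces data for
which that assumption is exactly true.

Two residual-variance conventions are provided:

* `sigma2_mode="paper"` (default): `σ̂² = ‖y − Xβ̂‖²/(m − 1)`, matching
  the convention of the published analysis of this cohort;
* `sigma2_mode="standard"`: the unbiased `‖y − Xβ̂‖²/(m − 4)`.

For `m = 14628` the two differ by <0.03%, below printed precision.
Contrast t-tests (`a1 = [0,−1,1,0]` for summer−kindergarten,
`a2 = [0,0,1,−1]` for summer−1st-grade) use `df = m − 4`. The source
analysis says "n − 4" without defining n; we read it as the score count
m because m is the only count entering the variance formula. At this
scale the choice is numerically irrelevant (t quantiles with df 3653 vs
14624 agree to ~4 decimals); the df used is recorded on every
`ContrastResult`.

## Stratification

Base categories (four home-reading frequencies; four income×education
groups) are disjoint and exhaustive; derived categories ("not every
day") are always materialized as unions of base partitions — the
published count algebra (86 + 752 + 1230 = 2068) identifies them as
derived, never raw. Each stratum is fit independently. A stratum too
small or degenerate for a rank-4 fit is flagged with an error status
without aborting the others (the never-read group, n = 86, is the
motivating case: its summer-rate SE is ±4.19). SES cutoffs (income above
185% of the federal poverty level; at least one parent with a bachelor's
degree) are carried as scheme metadata; the synthetic generator assigns
group labels directly.

## Scenario projection

A scenario is a contiguous sequence of dated regimes, each selecting one
fitted rate; the gain is the integral of the daily rate over the window,
so gains are additive over any interior split. Calendar defaults
(all configuration-visible):

| date | default | basis |
|---|---|---|
| projection window | 2020-01-01 → 2020-09-01 | stated analysis window (244 days) |
| closure start | 2020-03-16 | the week most U.S. schools closed |
| BAU school-year end | 2020-06-15 | not published; calibrated so the all-sample business-as-usual gain reproduces the printed 13.8 (166 d × 0.0717 + 78 d × 0.0246) |

Comparison metrics: rate decrease `(1 − β2/β1)·100`; gain loss
`(1 − closure/BAU)·100`; "points less" is measured against the
*all-sample* BAU gain of 13.8 for every group — forced by the published
arithmetic (13.8 − 10.6 = 3.2, 13.8 − 8.3 = 5.5); mitigation is the
share of the reference group's loss avoided, with "not every day" as the
reference (2.3/5.5 ≈ 42%). Gap-closing days between two strata is
`(β0_high − β0_low)/(β2_low − β2_high)·100` and is exact for noiseless
linear trajectories. All percentages are computed from unrounded
intermediates; rounding (gains to 1 decimal, percentages to integers)
happens only at display.

## Synthetic cohorts

The generator emulates the study's structure: 3657 children, exact
category counts (86/752/1230/1589 by reading frequency;
1307/167/678/1222 by SES, plus an unknown-SES remainder when labeling a
full cohort, since the SES subsample totals 3374), four assessments each,
scores from the piecewise model with independent Gaussian noise.
Defaults:

* **Assessment dates** — deterministic wave midpoints (mid-October,
  mid-April of each year); optional uniform jitter within two-month wave
  windows exercises date handling. The true wave dates of the 2010–11
  cohort are not published; midpoints are a stand-in, visible in config.
* **Calendar** — kindergarten 2010-09-15 → 2011-06-15, summer →
  2011-09-01; conventional U.S. school-year dates, config-visible, not
  published for the source cohort.
* **noise_sd = 13.0 points** — calibrated so that a full-size cohort
  under the midpoint design reproduces the published all-sample
  standard errors (≈0.18 / 0.51 / 0.18 per 100 days for the three
  rates). A single homoskedastic σ cannot also match the published
  intercept SE of 0.2 exactly (the implied σ is ~10); the slope SEs
  were preferred because every downstream result is about the rates.
* **PRNG** — `numpy.random.default_rng` (PCG64); one integer seed fully
  determines the output.

What the generator does *not* emulate: the two-stage adaptive assessment
and IRT score construction (scores are taken as given numbers), survey
weights and multistage sampling, attrition/missingness, within-child
score correlation, and heteroskedasticity across waves. Passing tests
therefore certify the estimator and projection machinery under the
model's own assumptions, not robustness to the ways real assessment data
violate them.

## Numerical and design choices

* Rates are stored per day internally and rescaled to per-100-days only
  at reporting, keeping the design matrix well conditioned in natural
  units; t statistics are invariant to this choice (tested).
* Zero-variance contrasts: an all-zero contrast reports NaN t and p;
  zero variance with a nonzero estimate raises.
* Degenerate inputs fail fast with typed errors: rank-deficient designs,
  records before the anchor date (offending children listed), regime
  gaps/overlaps, zero-denominator metrics (the metric is named).
* Exact-count category assignment is the default (matching the printed
  tables); proportions use largest-remainder rounding to hit the exact
  cohort size.
* The end-to-end pipeline (`run_full_analysis`) is a pure function of
  (input table, calendar, scheme, sigma2_mode, seed) and writes a
  byte-deterministic bundle; it logs retained/dropped children,
  per-stratum sizes, and the design condition number.

## Problem sizes

Zero-noise round-trip tests run at the full cohort size (3657 children,
14628 scores; the fit is a 4-parameter solve and takes milliseconds).
Confidence-interval coverage uses 200 replicate cohorts of 200 children
each — enough for a ±3-percentage-point Monte-Carlo band at 95%
nominal coverage.

## Known limitations and non-reproductions

* Between-group rate differences are compared descriptively, as in the
  source analysis; no formal interaction or multiple-comparison
  machinery is provided.
* Two published numbers are not reproduced by the published coefficients
  under the stated calendar, and the test suite asserts the mismatch
  rather than patching it: the never-read group's closure gain prints
  as 5.2 but the group's rates (7.71, −0.08 per 100 days) give ≈5.65;
  and the summary text's "5.6-point loss" for the not-every-day group
  conflicts with the body's 5.5 (the computed value, 5.54, rounds
  to 5.5).
* The pooled all-sample row of a published table is not the
  weighted mean of its category rows (as it would be for noiseless
  synthetic data under a shared design), so generative round trips
  recover the *category* rows exactly while pooled metrics from a mixed
  cohort differ slightly from the printed all-sample ones; paper
  reproduction therefore runs on the printed coefficients, which are
  inputs, not outputs, of the projection stage.
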