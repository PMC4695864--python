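# Methods

This note records the model behind `ablelife`, the choices made where the
estimation procedure leaves room, and what the synthetic cohort does and
does not establish about real panel data.

## Outcome definitions

All three outcomes live on a fixed follow-up window `W = 18` years with
scheduled waves at `0, Δ, 2Δ, …, W` (default `Δ = 1` year; `Δ = 0.5` is
supported, in which case transition matrices and incidence probabilities
are interpreted per grid step and hazards are scaled by `Δ`).

- **YOL**: `min(death time, W)`; `W` for survivors. Death times are
  continuous, so partial years count.
- **Healthy**: SRH in {Excellent, Very Good, Good}; not healthy: {Fair,
  Poor}. **Able**: no difficulty reported on any of the six ADL items
  (walking around the home, getting out of bed, eating, dressing,
  bathing, using the toilet); a single difficulty makes the year not
  able.
- **YHL / YAL**: trapezoidal integral of the recalibrated 0–100
  trajectory divided by 100.

## Recalibration

`score(s) = 100 · P(good next wave | state s now)`, estimated by pooling
every eligible consecutive-wave pair over all persons and waves
(complete-pair estimator: pairs whose next wave is unobserved are
dropped; fitting precedes imputation, so imputed values never feed the
scale). Death before the next scheduled wave is an eligible pair with
outcome 0, and the DEAD state itself is pinned to score 0. Ability is
keyed on the ADL difficulty count 0–6, the coarsest state that still
distinguishes severity.

Choices worth stating:

- *Next wave* means the next scheduled grid node, not a fixed calendar
  horizon.
- The recalibration is pooled across all waves and both sexes/races; no
  covariate-specific scales.
- A state with zero complete pairs has no score, and applying it is an
  error by default. The pipeline instead borrows the nearest scored state
  in the ordinal order, preferring the worse side so rare severe states
  (difficulty counts 4–6, typically support-free below ~10⁴ persons) are
  never scored optimistically. Fitted maps carry support counts so this
  is auditable.
- Fitted scores should decrease from best to worst state; violations are
  logged as data-quality warnings, never enforced.

## Imputation and the structural ADL gap

On the scored scale, interior runs of missing nodes are filled linearly
in time between the nearest observed neighbours (unique on an ordered
grid); leading runs take the first observed value, trailing runs the
last. Nodes at or after the death time are observed zeros and therefore
anchor interpolation. Completion is idempotent and never leaves the
convex hull of the observed values. Persons with no observed node at all
cannot be completed and are rejected.

The structural gap (default study years 11–15, during which the ADL
instrument is absent for everyone) is first imputed like any other gap
and then post-adjusted: a single cohort-level factor
`λ = mean(values at anchor years 10 and 16) / mean(imputed window
values)` multiplies every imputed in-window node, clipped to [0, 100].
Means are taken over person-nodes where the person is alive; persons dead
through the window contribute zeros that `λ` cannot change, which keeps
the adjustment consistent automatically. After adjustment the cohort
window mean equals the anchor mean exactly, minus whatever the clip at
100 removes (reported by the tests as "clipping loss"). The adjustment
could equally be person-level or additive; cohort-level multiplicative is
the simplest construction that satisfies the anchor-consistency
requirement, and an additive variant is available behind
`mode="additive"` for sensitivity analysis. Every imputed node carries a
provenance label (`interpolated`, `carried_back`, `carried_forward`,
`gap_adjusted`) in all outputs, so sensitivity analyses that exclude
imputed person-years are a one-line filter.

## Accumulation

The trapezoid rule is exact on piecewise-linear curves, which is what
recalibration + linear imputation produces, so the integral involves no
further approximation. Between the last grid node before death and the
death time the score falls linearly to zero (a node is inserted at the
death time), rather than stepping; this follows from treating the whole
completed trajectory as piecewise linear. YHL and YAL are computed on the
continuous probability scale rather than the binary indicator at observed
nodes — one convention throughout, a flag's difference if the binary
variant is wanted.

Consequences used as invariants: `0 ≤ YHL ≤ YOL` and `0 ≤ YAL ≤ YOL` per
person, and the per-group decomposition
`(18 − YOL) + (YOL − Y*) + Y* = 18` holds to machine precision.

## Summaries and regression

Group means carry normal-approximation CIs (`mean ± 1.96·SE`); group
sizes in the intended applications are hundreds to thousands, and the
bootstrap changes nothing material at that scale. Percent-of-remaining-
life columns are computed from unrounded means and then rounded half-up
to integers. The regression is plain OLS (no robust errors): outcome on
`(baseline age − 73)` plus indicators for white male, non-white female,
and non-white male; white female is the reference. CIs use the t
distribution with `n − p` degrees of freedom. Changing the centering age
shifts only the intercept (by the slope times the shift), which the tests
verify. An optional linear-spline diagnostic reports the R² gained by
letting age bend at knots 70/75/80; it is informational, not a gate. A
companion diagnostic table reports, within each sex×race stratum, the
spread across baseline-age bands of bad-state years versus good-state
years (the former is characteristically flat, the latter steep).

## Synthetic cohort generator

The generator is the package's test bed and default input. It emulates:

- **Composition**: 5888 persons split 47.4 / 36.3 / 10.2 / 6.1% into
  white female / white male / non-white female / non-white male, baseline
  ages drawn from 5-year bands (34.3 / 31.8 / 20.3 / 13.5% for 65–69 …
  80+; integer ages, the open band capped at 89).
- **SRH dynamics**: per-group 5×5 annual transition matrices, diagonally
  dominant, with an additive per-year-of-age shift of probability mass
  one category toward worse (renormalized). Non-white groups start worse
  and transition worse.
- **ADL items**: six independent items per person; difficulty is
  acquired at a per-item annual probability growing exponentially with
  age and recovered at a constant probability.
- **Mortality**: Gompertz hazard `rate · exp(0.095 · (age − 65))` per
  group, death uniform within the year of the event, absorbing.
- **Missingness**: each non-baseline wave is skipped independently with
  probability 0.30 (missing completely at random; SRH and ADL vanish
  together, vital status never does), and all ADL items are masked in
  the structural window years 11–15.

Default rates were fixed once, before the test suite existed, against the
study conditions the generator emulates: Gompertz rates solved by
bisection on the closed-form truncated mean survival so group mean YOL is
≈ 13.1 / 11.0 / 12.5 / 10.4 years; SRH and ADL dynamics set so the cohort
spends ≈ 69% of remaining life healthy and ≈ 75% able; the missingness
rate set so ≈ 45% of observed responses flank an intervening missing
value (measured by brute-force scan, which at rate m ≈ 1 − (1 − m)² in
the interior). A 2000-person default run lands within about 0.2 years
and 1–2 percentage points of those values.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real cohorts: informative (health- or
death-related) missingness (a health-dependent mechanism is a
deliberately unused knob), dependence among ADL items, semi-annual
contact cadence mixed with annual ADL measurement, staggered enrollment
of a second cohort in calendar time, geographic site effects, and
reporting heterogeneity across groups. The acceptance checks on
published coefficient tables are arithmetic reproductions of the
reported worked examples, not re-estimations from the original data,
which are not public.

## Problem sizes and numerics

The test suite runs cohorts of 300–10,000 persons: 10,000 for
calibration-style checks (transition frequencies, closed-form
recalibration scores, closed-form mean survival, the 45% missingness
scan), 2,000 × 500 replicates for OLS CI coverage, and smaller cohorts
for end-to-end runs — sizes at which the binomial/SE tolerances the tests
use (3 standard errors; coverage within 93–97%) are discriminating.
Floating-point specifics: grid times are rounded to 10 decimals for node
matching; death comparisons use a 1e-9 slack; trajectory completion via
piecewise-linear interpolation matches an independent neighbour-scan
oracle to ≤ 1e-12; the trapezoid matches a step-1e-4 midpoint Riemann sum
to 1e-6 years. Degenerate inputs are errors, not silent defaults: empty
cohorts, trajectories with no observations, a zero window mean under a
nonzero anchor mean, rank-deficient designs (reported with the offending
column), unknown state labels, and waves after death.
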