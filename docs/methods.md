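# Methods

This note documents the model implemented in `htncea`, its assumptions, the
numerical conventions chosen where the problem is genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## Model structure

The evaluation compares two arms over a 12-year window: a two-year
implementation phase (decision tree) followed by a ten-year projection
(Markov cohort model). The *factual* arm uses the blood-pressure control
rate measured at the end of the program; the *counterfactual* arm holds the
baseline control rate, representing usual care. Control rates are held
constant within each arm — no ramp-up during implementation and no further
programmatic benefit afterwards, a deliberately conservative convention.

All arithmetic is deterministic expected-value cohort accounting: occupancies
are real-valued expected counts, not random draws. The only stochastic
component in the package is the validation microsimulation (below).

### Event machinery

- Ten-year CVD risks per sex × risk category are annualized with the
  constant-hazard transform `p = 1 − (1 − r10)^(1/10)`, the standard
  convention for annual-cycle Markov models. The transform is exact under a
  time-homogeneous hazard; it slightly front-loads risk relative to an
  age-increasing hazard.
- Controlled patients' annual event probability is multiplied by a hazard
  ratio stratified by sex and initial-BP band. Patient-level BP is not
  available in cohort mode, so the band is derived from the risk category
  through a configurable mapping (identity by default).
- A fixed stroke fraction (default 0.30) splits total CVD events into
  strokes and CHD events.
- Events are cycle tolls: the three-state space has no post-event state, so
  an event accrues its acute cost and its disutility in the event year and
  the patient remains in their control state. Multi-year event sequelae
  would require tunnel states and are out of scope.

### Mortality

Annual death probabilities come from a national life table `q(a)` (CSV,
columns `age,qx`, 1-year steps; lookups clamp at the table edges).
Uncontrolled hypertension carries a multiplier κ (default 3.0). Two modes:

- **calibrated** (default): `q_c(a) = q(a) / (1 − u₀ + κ·u₀)`,
  `q_u(a) = κ·q_c(a)`, where `u₀` is the *baseline* uncontrolled share.
  A population at the baseline control mix then reproduces the national
  life table exactly, anchoring all-cause mortality to observed data, while
  an arm with more controlled patients accrues genuinely fewer deaths. The
  anchor mix must be arm-independent: calibrating with each arm's own mix
  would force every arm's total deaths to `alive × q(a)` and erase the
  survival benefit entirely.
- **direct**: `q_c = q(a)`, `q_u = κ·q(a)`. Simpler, but the population
  mortality then exceeds the life table whenever anyone is uncontrolled.

Probabilities are capped at 1 with a warning.

During the implementation phase both arms share one mortality stream at the
baseline control mix, so phase deaths are identical across arms. Rationale:
over one to two years, differential mortality from BP control is too small
to resolve, and the comparison should attribute no short-term death benefit.

### Control-status dynamics in the projection

The transition probabilities between controlled and uncontrolled states are
not identifiable from cohort summaries, so two bracketing modes exist:

- **static** (default): survivors keep their control status. The observed
  control fraction among survivors then drifts upward because uncontrolled
  patients die faster.
- **rebalance**: survivors are re-apportioned each cycle so the control
  fraction stays exactly at its projection-entry value.

Both run through the same accounting; tests cover both.

### Aging

A single cohort mean age advances one year per cycle. No age distribution is
tracked; the life table and utility bands are evaluated at the (integer
rounded) mean age. This matches the mean-age-driven sensitivity analysis and
keeps the model a 3-state chain, at the cost of Jensen-gap bias for strongly
convex `q(a)`.

## Economics

- **Costs** (societal perspective): annual hypertension health-state cost per
  alive person-year (identical for controlled and uncontrolled, so state
  costs differ between arms only through survival), acute per-event costs for
  CHD and stroke, an annual productivity loss accruing to uncontrolled
  person-years only, and the program cost, applied once and undiscounted to
  the factual arm. `direct_costs` and `running_costs_after_implementation`
  are optional line items (default 0) so the full sensitivity-parameter list
  is addressable.
- **Unit-cost transfer**: cities without local cost estimates divide the
  reference city's (São Paulo's) values by a purchasing-power-parity factor,
  rounded to whole USD.
- **QALYs**: alive person-years weighted by age-band utilities
  (0.84 / 0.82 / 0.78 / 0.74 for ages 50–59 / 60–69 / 70–79 / 80–100; ages
  below 50 clamp to the first band with a warning) minus per-event
  disutilities (CHD 0.018, stroke 0.048) in the event year.
- **Discounting**: projection cycle *t* is discounted by `(1 + d)^(−t)`;
  the implementation phase is the costing baseline period and is
  undiscounted. Default rates: 3% (Ulaanbaatar, Dakar), 5% (São Paulo).
- **Person-year accounting**: whole-cycle, on cycle-start occupancies,
  consistent with the absence of a half-cycle correction.
- **ICER** = ΔCost / ΔQALY at full precision (display rounding to whole USD
  only in exported tables); undefined and flagged when ΔQALY ≤ 0. Verdicts:
  below the adjusted threshold band → yes, above it → no, inside → unclear;
  the WHO-CHOICE verdict compares against 3 × per-capita GDP. The breakeven
  year is the first cycle at which cumulative counterfactual costs reach the
  cumulative factual costs (program cost included at period 0).

Because productivity losses attach to *all* uncontrolled person-years, they
dominate incremental costs when the control-rate gain is large (São Paulo's
preset is strongly cost-saving under the defaults). Analyses that prefer a
narrower payer perspective can set `productivity_loss_annual` to 0.

## Sensitivity analysis

One-way perturbation: each parameter is set to ×(1−δ) and ×(1+δ) (default
δ = 0.10) holding everything else fixed, the full pipeline reruns, and
parameters are sorted by descending ICER swing (tornado order). Conventions:
mean age is perturbed by ±10% and rounded to whole years (the life-table and
utility machinery is discrete); `utility` scales all age-band utilities
jointly (capped at 1.0) and `disutility` both event disutilities jointly;
cohort size is rounded to a whole patient count and does not rescale the
program cost, which is a total.

## Synthetic data and validation

`make_cohort` samples patient-level records (sex, risk category, age, and
comonotone control flags for the two arms — a patient controlled at baseline
stays controlled under the higher end rate) and returns the *empirical*
cohort summary, so cohort arithmetic is exactly consistent with the sample.
`make_life_table` generates Gompertz life tables
`qx(a) = 1 − exp(−a·e^(b·age))`; the presets ship such tables (files named
`life_table_synthetic_*`) as stand-ins for national mortality data. The
generator does not emulate clinic-level heterogeneity, visit schedules,
within-category BP variation, or missingness.

`microsim_oracle` replays the projection as independent annual Bernoulli
draws per patient — event draws at the cohort per-state probabilities, death
draws at the calibrated per-state probabilities, event type by a stroke-
fraction draw — under static control dynamics. Its replicate means estimate
the same expectations the deterministic model computes in closed form, so
agreement within Monte-Carlo error (the suite requires 3 SEs at n = 2,000,
500 replicates) validates the Markov bookkeeping from first principles.
Because the per-patient probabilities are the cohort model's own per-state
values, the check validates the accounting (depletion, mixing, cumulative
sums), not the stratum-aggregation step, which is covered by direct unit
tests instead.

Passing tests on synthetic cohorts therefore demonstrate internal
consistency of the machinery, not the external validity of any particular
risk input.

## Problem sizes and defaults

Preset runs use the published cohort sizes (5,236–10,075 patients; these are
expected-value computations, so size affects only scale). The
oracle-equivalence check uses a 2,000-patient synthetic cohort with 500
Monte-Carlo replicates over 10 cycles, large enough that 3 SEs is a tight
bound (z-scores observed well below 1) while running in seconds.

## Illustrative preset inputs

The shipped presets carry published values for everything printed at city
level: cohort sizes, sex fractions, mean ages, control rates, unit costs,
program costs, PPP factors, discount rates, utilities, disutilities,
threshold bands, and GDP per capita. The per-stratum 10-year risks, hazard
ratios, and risk-category distributions are *illustrative* Framingham-style
defaults (documented in each preset file), and the life tables are synthetic:
the original stratum-level inputs are not public. Consequently absolute event
counts from the presets are indicative; the reporting identities, threshold
logic, and all structural properties are exact.

## Known limitations

- Three states only: no post-event morbidity states, no re-screening, no
  time-varying control rates.
- CVD events add no excess mortality beyond the life-table × multiplier
  mechanism (no event-death pathway exists in the state space).
- Event disutilities apply in the event year only.
- Mean-age aging ignores the cohort's age dispersion.
- The implementation phase is fixed at two annual steps regardless of the
  per-city reporting-period length stored in the preset (kept for context
  and sensitivity use).
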