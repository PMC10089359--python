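# htncea

Cohort-level health-economic evaluation of urban hypertension-control
programs: a decision-tree model for the implementation phase, a three-state
Markov cohort model for the ten-year projection, and a costing/QALY layer
producing incremental cost-effectiveness ratios (ICERs), threshold verdicts,
and one-way (tornado) sensitivity analyses.

## Who this is for

Health economists and epidemiologists who need to translate observed changes
in blood-pressure control rates — the typical primary outcome of a city- or
clinic-level hypertension initiative — into expected cardiovascular events
averted, quality-adjusted life years (QALYs) gained, and cost per QALY,
without patient-level longitudinal data.

## The model

A treated hypertensive cohort is summarized by its size *n*, male fraction,
mean age, distribution over three cardiovascular-risk categories
(low/medium/high), and blood-pressure control rates before (*c₀*) and after
(*c₁*) the program.

**Event risk.** Ten-year CVD risks *r₁₀(s, k)* per sex *s* and risk category
*k* (Framingham-style inputs) are annualized under a constant hazard,
*p = 1 − (1 − r₁₀)^(1/10)*. Controlled patients enjoy hazard ratios
*HR(s, b) < 1* stratified by sex and initial-BP band. The cohort-level annual
event probability at control rate *c* is

```
p(c) = Σ_{s,k} w(s,k) · p(s,k) · [(1 − c) + c · HR(s, b(k))]
```

A fixed fraction φ of events are strokes, the rest coronary heart disease
(CHD) events. Events are *tolls*: they accrue costs and disutility but do not
move patients between states.

**Implementation phase (decision tree).** Two annual steps with the factual
arm at *c₁* and the counterfactual arm at *c₀*. Deaths follow the national
life table under the baseline control mix in both arms, so phase deaths are
identical across arms by construction.

**Ten-year projection (Markov model).** States: controlled, uncontrolled,
dead; annual cycles; no half-cycle correction. Death probabilities come from
a life table *q(a)*, differentiated by control status via a multiplier κ
(uncontrolled ≈ 3× controlled) calibrated so that a population at the
baseline control mix reproduces *q(a)*:

```
q_c(a) = q(a) / (1 − u₀ + κ·u₀),     q_u(a) = κ · q_c(a),   u₀ = 1 − c₀
```

**Economics.** Discounted costs (health-state, per-event, productivity losses
for uncontrolled person-years, program cost in the factual arm) and QALYs
(age-band utilities minus per-event disutilities) yield
ICER = ΔCost / ΔQALY, compared against a PPP/opportunity-cost-adjusted
threshold band and the WHO-CHOICE bar of 3× per-capita GDP.

Three city scenario presets ship with the package (`ulaanbaatar`, `dakar`
with a `dakar_alt` baseline variant, and `sao_paulo`). Their cohort sizes,
control rates, unit costs, utilities, thresholds, and program costs are the
published city values; the risk-stratum inputs and life tables are clearly
labelled illustrative/synthetic stand-ins, since the underlying patient data
are confidential.

## Worked example

```python
from htncea import HypertensionCEModel

res = HypertensionCEModel.from_preset("ulaanbaatar").fit()
print(res.summary())
```

prints

```
Hypertension program cost-effectiveness — Ulaanbaatar
  cohort: n=10,075, mean age 61, male fraction 0.37
  control rate: 3% (baseline) -> 19% (end of implementation)

Implementation phase (2 years)
event_type  counterfactual  factual  averted  percent_averted  ...
       CHD           129.6    123.2      6.4              5.0  ...
    Stroke            55.5     52.8      2.8              5.0  ...
    Deaths           277.9    277.9      0.0              0.0  ...

Ten-year projection (10 cycles, static control dynamics)
event_type  counterfactual  factual  averted  percent_averted  ...
       CHD           580.0    555.2     24.8              4.3  ...
    Stroke           248.6    237.9     10.6              4.3  ...
    Deaths          2085.4   1866.9    218.5             10.5  ...

Cost-effectiveness
                            quantity       value
              Incremental cost (USD)      249905
                   Incremental QALYs         572
          ICER (USD per QALY gained)         437
ICER threshold (USD per QALY gained) 1,624-4,849
  WHO-CHOICE threshold (3x GDP, USD)       12405
 Cost-effective (adjusted threshold)         yes
         Cost-effective (WHO-CHOICE)         yes
                           Breakeven          No
```

Reading: raising control from 3% to 19% averts ~6 CHD events and ~3 strokes
during the two implementation years (deaths are shared across arms in this
phase by design), and over the following decade averts ~25 CHD events, ~11
strokes, and ~219 premature deaths among the 10,075 treated patients. The
program costs USD 249,905 more than usual care after event-cost and
productivity offsets, gains 572 discounted QALYs, and its ICER of USD
437/QALY falls below both the adjusted threshold band (1,624–4,849) and the
WHO-CHOICE bar — the intervention is cost-effective under these inputs.
Event counts depend on the preset's illustrative risk strata; the arithmetic
identities (percent averted, per-1,000 rates, ICER quotients, PPP transfers,
thresholds) are exact.

The same pipeline is scriptable:

```bash
htncea run --preset sao_paulo --out results/sao_paulo
htncea run-all --out results/all
htncea sensitivity --preset dakar --out results/dakar_tornado.csv
htncea simulate --seed 1          # microsimulation check of the cohort model
```

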