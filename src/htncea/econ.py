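"""Costing, QALYs, discounting, ICERs, and threshold verdicts.

Costs are taken from a societal perspective: annual hypertension health-state
costs per alive patient-year, per-event acute costs for CHD and stroke,
productivity losses accruing to uncontrolled patient-years only, and the
program's implementation cost (factual arm only).  Unit costs for cities
without local estimates are transferred from a reference city through
purchasing-power-parity (PPP) division.

QALYs weight alive person-time by an age-band utility and subtract per-event
disutilities in the event year.  Projection cycle ``t`` is discounted by
``(1 + d)^-t``; the implementation phase is the costing baseline period and
is undiscounted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .decision_tree import PhaseResult
from .markov import ProjectionTrace

__all__ = [
    "EconParameters",
    "CEAResult",
    "ppp_convert",
    "discount_factor",
    "utility_for_age",
    "arm_costs",
    "arm_qalys",
    "compare_arms",
]

_DEFAULT_UTILITIES = {"50-59": 0.84, "60-69": 0.82, "70-79": 0.78, "80-100": 0.74}
_DEFAULT_DISUTILITIES = {"chd": 0.018, "stroke": 0.048}


class EconParameters(BaseModel):
    """Cost, utility, discounting, and threshold inputs (USD)."""

    model_config = ConfigDict(validate_assignment=True)

    annual_htn_cost: float = Field(ge=0.0)
    chd_event_cost: float = Field(ge=0.0)
    stroke_event_cost: float = Field(ge=0.0)
    productivity_loss_annual: float = Field(ge=0.0)
    program_cost_total: float = Field(ge=0.0)
    program_cost_accrual: str = "once"  # applied once, undiscounted
    direct_costs: float = Field(default=0.0, ge=0.0)
    running_costs_after_implementation: float = Field(default=0.0, ge=0.0)
    ppp_factor: float = Field(default=1.0, gt=0.0)
    discount_rate: float = Field(ge=0.0, lt=1.0)
    age_band_utilities: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_UTILITIES)
    )
    event_disutility: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_DISUTILITIES)
    )
    icer_threshold_low: float = Field(gt=0.0)
    icer_threshold_high: float = Field(gt=0.0)
    gdp_per_capita: float = Field(gt=0.0)

    @field_validator("age_band_utilities")
    @classmethod
    def _check_utils(cls, v):
        parsed = {}
        for band, u in v.items():
            lo, hi = band.split("-")
            if int(lo) > int(hi):
                raise ValueError(f"malformed age band {band!r}")
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility must be in [0, 1], got {u} for band {band}")
            parsed[band] = u
        if not parsed:
            raise ValueError("age_band_utilities must not be empty")
        return parsed

    @field_validator("event_disutility")
    @classmethod
    def _check_disutils(cls, v):
        for k in ("chd", "stroke"):
            if k not in v:
                raise ValueError(f"event_disutility missing {k!r}")
            if v[k] < 0:
                raise ValueError(f"disutility must be non-negative, got {v[k]} for {k}")
        return v

    @property
    def who_choice_threshold(self) -> float:
        """WHO-CHOICE willingness-to-pay bar: 3x national per-capita GDP."""
        return 3.0 * self.gdp_per_capita


@dataclass
class CEAResult:
    """Paired-arm cost-effectiveness comparison over phase + projection."""

    incremental_cost: float
    incremental_qalys: float
    icer: float | None  # None when incremental QALYs <= 0
    cost_effective_adjusted: str  # yes / no / unclear
    cost_effective_whochoice: str
    breakeven_year: int | None
    events_averted_by_type: dict[str, float]
    cohort_n: float
    cost_factual: float = 0.0
    cost_counterfactual: float = 0.0
    qalys_factual: float = 0.0
    qalys_counterfactual: float = 0.0

    @property
    def incremental_qalys_per_1000(self) -> float:
        return 1000.0 * self.incremental_qalys / self.cohort_n

    def to_dict(self) -> dict:
        d = {
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "incremental_qalys_per_1000": self.incremental_qalys_per_1000,
            "icer": self.icer,
            "cost_effective_adjusted": self.cost_effective_adjusted,
            "cost_effective_whochoice": self.cost_effective_whochoice,
            "breakeven_year": self.breakeven_year,
            "events_averted_by_type": dict(self.events_averted_by_type),
        }
        return d


def ppp_convert(cost_reference: float, ppp_factor: float) -> int:
    """Transfer a reference-city unit cost by PPP division, to whole USD."""
    if ppp_factor <= 0:
        raise ValueError(f"ppp_factor must be positive, got {ppp_factor}")
    return round(cost_reference / ppp_factor)


def discount_factor(rate: float, cycle: int) -> float:
    """Discount factor ``(1 + rate)^-cycle`` for projection cycle >= 1."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    return (1.0 + rate) ** (-cycle)


def utility_for_age(age: float, bands: dict[str, float]) -> float:
    """Age-band utility lookup; ages outside the bands clamp to the nearest."""
    parsed = sorted(
        ((int(b.split("-")[0]), int(b.split("-")[1]), u) for b, u in bands.items())
    )
    a = age
    lo0 = parsed[0][0]
    hi_last = parsed[-1][1]
    if a < lo0:
        warnings.warn(
            f"age {age} below the first utility band; clamped to {parsed[0][0]}-{parsed[0][1]}",
            stacklevel=2,
        )
        return parsed[0][2]
    if a > hi_last:
        return parsed[-1][2]
    for lo, hi, u in parsed:
        if lo <= a <= hi:
            return u
    # gap between bands: use the band below
    below = [p for p in parsed if p[1] < a]
    return below[-1][2]


def arm_costs(
    phase: PhaseResult,
    trace: ProjectionTrace,
    econ: EconParameters,
    include_program: bool,
) -> float:
    """Total discounted cost of one arm over phase + projection."""
    return float(_cost_series(phase, trace, econ, include_program).sum())


def _cost_series(
    phase: PhaseResult,
    trace: ProjectionTrace,
    econ: EconParameters,
    include_program: bool,
) -> pd.Series:
    """Per-period discounted costs, indexed 0 (phase) then 1..T (cycles)."""
    phase_cost = (
        phase.person_years * econ.annual_htn_cost
        + phase.chd_events * econ.chd_event_cost
        + phase.stroke_events * econ.stroke_event_cost
        + phase.uncontrolled_person_years * econ.productivity_loss_annual
    )
    if include_program:
        phase_cost += econ.program_cost_total + econ.direct_costs

    costs = {0: phase_cost}
    for _, row in trace.records.iterrows():
        t = int(row["cycle"])
        alive_start = row["controlled_start"] + row["uncontrolled_start"]
        cycle_cost = (
            alive_start * econ.annual_htn_cost
            + row["chd_events"] * econ.chd_event_cost
            + row["stroke_events"] * econ.stroke_event_cost
            + row["uncontrolled_start"] * econ.productivity_loss_annual
        )
        if include_program:
            cycle_cost += econ.running_costs_after_implementation
        costs[t] = cycle_cost * discount_factor(econ.discount_rate, t)
    return pd.Series(costs).sort_index()


def arm_qalys(phase: PhaseResult, trace: ProjectionTrace, econ: EconParameters) -> float:
    """Total discounted QALYs of one arm over phase + projection."""
    return float(_qaly_series(phase, trace, econ).sum())


def _qaly_series(phase: PhaseResult, trace: ProjectionTrace, econ: EconParameters) -> pd.Series:
    d_chd = econ.event_disutility["chd"]
    d_str = econ.event_disutility["stroke"]
    if phase.records is not None:
        phase_q = sum(
            row["alive_start"] * utility_for_age(row["age"], econ.age_band_utilities)
            - row["chd_events"] * d_chd
            - row["stroke_events"] * d_str
            for _, row in phase.records.iterrows()
        )
    else:
        # aggregate fallback for hand-built PhaseResults without step records
        phase_age = phase.end_age - 1.0
        phase_q = (
            phase.person_years * utility_for_age(phase_age, econ.age_band_utilities)
            - phase.chd_events * d_chd
            - phase.stroke_events * d_str
        )
    qalys = {0: phase_q}
    for _, row in trace.records.iterrows():
        t = int(row["cycle"])
        alive = row["controlled_start"] + row["uncontrolled_start"]
        q = (
            alive * utility_for_age(row["age"], econ.age_band_utilities)
            - row["chd_events"] * d_chd
            - row["stroke_events"] * d_str
        )
        qalys[t] = q * discount_factor(econ.discount_rate, t)
    return pd.Series(qalys).sort_index()


def _verdict(icer: float | None, low: float, high: float) -> str:
    if icer is None:
        return "unclear"
    if icer < 0:
        return "yes"  # cost-saving with QALY gain dominates
    if icer <= low:
        return "yes"
    if icer > high:
        return "no"
    return "unclear"


def compare_arms(
    factual: tuple[PhaseResult, ProjectionTrace],
    counterfactual: tuple[PhaseResult, ProjectionTrace],
    econ: EconParameters,
) -> CEAResult:
    """Incremental cost, QALYs, ICER, threshold verdicts, and breakeven year.

    The factual arm carries the program cost; the counterfactual does not.
    The breakeven year is the first projection cycle at which cumulative
    counterfactual costs reach or exceed cumulative factual costs.
    """
    phase_f, trace_f = factual
    phase_cf, trace_cf = counterfactual
    if abs(phase_f.n_patients - phase_cf.n_patients) > 1e-6:
        raise ValueError("arms describe different cohort sizes")

    cost_f_series = _cost_series(phase_f, trace_f, econ, include_program=True)
    cost_cf_series = _cost_series(phase_cf, trace_cf, econ, include_program=False)
    cost_f = float(cost_f_series.sum())
    cost_cf = float(cost_cf_series.sum())
    qaly_f = arm_qalys(phase_f, trace_f, econ)
    qaly_cf = arm_qalys(phase_cf, trace_cf, econ)

    d_cost = cost_f - cost_cf
    d_qaly = qaly_f - qaly_cf
    if d_qaly > 0:
        icer = d_cost / d_qaly
    else:
        icer = None
        warnings.warn("incremental QALYs <= 0; ICER undefined", stacklevel=2)

    cum_f = cost_f_series.cumsum()
    cum_cf = cost_cf_series.cumsum()
    breakeven = None
    for t in cum_f.index:
        if t >= 1 and cum_cf.loc[t] >= cum_f.loc[t]:
            breakeven = int(t)
            break

    averted = {
        "chd": (phase_cf.chd_events + trace_cf.total_chd)
        - (phase_f.chd_events + trace_f.total_chd),
        "stroke": (phase_cf.stroke_events + trace_cf.total_stroke)
        - (phase_f.stroke_events + trace_f.total_stroke),
        "deaths": (phase_cf.deaths + trace_cf.total_deaths)
        - (phase_f.deaths + trace_f.total_deaths),
    }

    return CEAResult(
        incremental_cost=d_cost,
        incremental_qalys=d_qaly,
        icer=icer,
        cost_effective_adjusted=_verdict(icer, econ.icer_threshold_low, econ.icer_threshold_high),
        cost_effective_whochoice=_verdict(
            icer, econ.who_choice_threshold, econ.who_choice_threshold
        ),
        breakeven_year=breakeven,
        events_averted_by_type=averted,
        cohort_n=phase_f.n_patients,
        cost_factual=cost_f,
        cost_counterfactual=cost_cf,
        qalys_factual=qaly_f,
        qalys_counterfactual=qaly_cf,
    )
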