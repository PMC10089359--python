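"""Two-year implementation-phase decision tree.

Estimates expected CHD events, strokes, and deaths for the intervention
("factual") and usual-care ("counterfactual") arms over the program's
implementation phase, and produces the end-of-phase state distribution that
seeds the 10-year Markov projection.

Accounting rules
----------------
* The phase is modelled as two annual steps with the arm's control rate held
  fixed from step 1 (the factual arm uses the end-of-period control rate, the
  counterfactual the baseline rate).
* Events are tolls: they accrue costs and disutility without removing
  patients from the cohort.  Only death depletes it.
* Deaths use the *baseline* control mix in both arms, so implementation-phase
  deaths are identical across arms by construction; the short phase is
  assumed too brief for differential mortality to materialize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import CohortProfile
from .risk import RiskParameters, cohort_state_rates, mortality_probs, split_events

__all__ = ["PhaseResult", "AvertedSummary", "run_implementation_phase", "events_averted", "PHASE_YEARS"]

PHASE_YEARS = 2  # decision-tree horizon, annual steps


@dataclass(frozen=True)
class PhaseResult:
    """Expected implementation-phase outcomes for one scenario arm.

    ``records`` holds one row per annual step (age, cycle-start alive,
    uncontrolled person-years, events, deaths) for costing and QALY accrual.
    """

    arm_label: str
    chd_events: float
    stroke_events: float
    deaths: float
    end_controlled: float
    end_uncontrolled: float
    end_age: float
    person_years: float
    uncontrolled_person_years: float
    records: pd.DataFrame = field(default=None, repr=False, compare=False)

    @property
    def n_patients(self) -> float:
        return self.end_controlled + self.end_uncontrolled + self.deaths

    @property
    def survivors(self) -> float:
        return self.end_controlled + self.end_uncontrolled


@dataclass(frozen=True)
class AvertedSummary:
    """Arm comparison for one event type."""

    event_type: str
    counterfactual: float
    factual: float
    averted: float
    percent_averted: float
    per_1000_counterfactual: float
    per_1000_factual: float
    per_1000_averted: float


def run_implementation_phase(
    profile: CohortProfile, risk: RiskParameters, arm: str
) -> PhaseResult:
    """Run the decision tree for one arm.

    ``arm`` is ``"factual"`` (program present; end-of-period control rate) or
    ``"counterfactual"`` (program absent; baseline control rate).
    """
    if arm == "factual":
        control_rate = profile.control_rate_end
    elif arm == "counterfactual":
        control_rate = profile.control_rate_baseline
    else:
        raise ValueError(f"arm must be 'factual' or 'counterfactual', got {arm!r}")

    p_unc, p_ctl = cohort_state_rates(profile, risk)
    event_rate = (1.0 - control_rate) * p_unc + control_rate * p_ctl

    # shared mortality stream: baseline control mix in both arms
    u_baseline = 1.0 - profile.control_rate_baseline

    alive = float(profile.n_patients)
    chd = stroke = deaths = 0.0
    person_years = 0.0
    rows = []
    for step in range(PHASE_YEARS):
        age = profile.mean_age + step
        q_c, q_u = mortality_probs(
            age,
            risk.life_table,
            risk.mortality_multiplier_uncontrolled,
            u_baseline,
            mode=risk.mortality_mode,
        )
        q_mix = (1.0 - u_baseline) * q_c + u_baseline * q_u
        step_events = alive * event_rate
        step_chd, step_stroke = split_events(step_events, risk.stroke_fraction)
        chd += step_chd
        stroke += step_stroke
        step_deaths = alive * q_mix
        deaths += step_deaths
        person_years += alive
        rows.append(
            {
                "step": step + 1,
                "age": age,
                "alive_start": alive,
                "uncontrolled_start": alive * (1.0 - control_rate),
                "chd_events": step_chd,
                "stroke_events": step_stroke,
                "deaths": step_deaths,
            }
        )
        alive -= step_deaths

    return PhaseResult(
        arm_label=arm,
        chd_events=chd,
        stroke_events=stroke,
        deaths=deaths,
        end_controlled=alive * control_rate,
        end_uncontrolled=alive * (1.0 - control_rate),
        end_age=profile.mean_age + PHASE_YEARS,
        person_years=person_years,
        uncontrolled_person_years=person_years * (1.0 - control_rate),
        records=pd.DataFrame(rows),
    )


def _averted(event_type: str, cf: float, f: float, n: float) -> AvertedSummary:
    averted = cf - f
    percent = 100.0 * averted / cf if cf > 0 else 0.0
    return AvertedSummary(
        event_type=event_type,
        counterfactual=cf,
        factual=f,
        averted=averted,
        percent_averted=percent,
        per_1000_counterfactual=1000.0 * cf / n,
        per_1000_factual=1000.0 * f / n,
        per_1000_averted=1000.0 * averted / n,
    )


def events_averted(
    counterfactual: PhaseResult, factual: PhaseResult
) -> dict[str, AvertedSummary]:
    """Compare the two arms' phase outcomes per event type.

    Returns summaries keyed ``"chd"``, ``"stroke"``, ``"deaths"``.  Rounding
    (counts to integers, percents and per-1,000 rates to one decimal) is a
    display concern and is not applied here.
    """
    if abs(counterfactual.n_patients - factual.n_patients) > 1e-6:
        raise ValueError(
            "arms describe different cohort sizes: "
            f"{counterfactual.n_patients} vs {factual.n_patients}"
        )
    n = counterfactual.n_patients
    return {
        "chd": _averted("chd", counterfactual.chd_events, factual.chd_events, n),
        "stroke": _averted("stroke", counterfactual.stroke_events, factual.stroke_events, n),
        "deaths": _averted("deaths", counterfactual.deaths, factual.deaths, n),
    }
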