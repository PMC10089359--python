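"""One-way (tornado) sensitivity analysis of the ICER.

Each named parameter is varied by a fixed fraction (default +/-10%) holding
everything else at baseline, the full pipeline is rerun, and parameters are
ranked by the absolute ICER swing between the low and high runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .econ import EconParameters
from .params import CohortProfile
from .pipeline import run_scenario
from .risk import RiskParameters

__all__ = ["TornadoEntry", "one_way_sensitivity", "DEFAULT_PARAMETERS", "tornado_frame"]

Scenario = tuple[CohortProfile, RiskParameters, EconParameters]


@dataclass(frozen=True)
class TornadoEntry:
    parameter_name: str
    icer_low: float
    icer_high: float
    baseline_icer: float
    swing: float


def _scale_econ(field: str) -> Callable[[Scenario, float], Scenario]:
    def perturb(scenario: Scenario, factor: float) -> Scenario:
        profile, risk, econ = scenario
        return profile, risk, econ.model_copy(update={field: getattr(econ, field) * factor})

    return perturb


def _perturb_n(scenario: Scenario, factor: float) -> Scenario:
    profile, risk, econ = scenario
    n = max(1, round(profile.n_patients * factor))
    return profile.model_copy(update={"n_patients": n}), risk, econ


def _perturb_age(scenario: Scenario, factor: float) -> Scenario:
    # rounded to whole years to match the discrete life-table / utility-band machinery
    profile, risk, econ = scenario
    age = float(round(profile.mean_age * factor))
    return profile.model_copy(update={"mean_age": age}), risk, econ


def _perturb_utility(scenario: Scenario, factor: float) -> Scenario:
    profile, risk, econ = scenario
    bands = {b: min(1.0, u * factor) for b, u in econ.age_band_utilities.items()}
    return profile, risk, econ.model_copy(update={"age_band_utilities": bands})


def _perturb_disutility(scenario: Scenario, factor: float) -> Scenario:
    profile, risk, econ = scenario
    dis = {k: v * factor for k, v in econ.event_disutility.items()}
    return profile, risk, econ.model_copy(update={"event_disutility": dis})


def _perturb_risk(scenario: Scenario, factor: float) -> Scenario:
    profile, risk, econ = scenario
    risks = {
        sex: {cat: min(0.999999, r * factor) for cat, r in cats.items()}
        for sex, cats in risk.ten_year_cvd_risk.items()
    }
    return profile, risk.model_copy(update={"ten_year_cvd_risk": risks}), econ


_REGISTRY: dict[str, Callable[[Scenario, float], Scenario]] = {
    "n_patients": _perturb_n,
    "mean_age": _perturb_age,
    "annual_htn_cost": _scale_econ("annual_htn_cost"),
    "chd_event_cost": _scale_econ("chd_event_cost"),
    "stroke_event_cost": _scale_econ("stroke_event_cost"),
    "productivity_loss_annual": _scale_econ("productivity_loss_annual"),
    "program_cost": _scale_econ("program_cost_total"),
    "direct_costs": _scale_econ("direct_costs"),
    "running_costs_after_implementation": _scale_econ("running_costs_after_implementation"),
    "utility": _perturb_utility,
    "disutility": _perturb_disutility,
    "cvd_risk": _perturb_risk,
}

DEFAULT_PARAMETERS = (
    "n_patients",
    "mean_age",
    "direct_costs",
    "running_costs_after_implementation",
    "annual_htn_cost",
    "chd_event_cost",
    "stroke_event_cost",
    "productivity_loss_annual",
    "program_cost",
    "utility",
    "disutility",
)


def one_way_sensitivity(
    scenario: Scenario,
    parameter_list: tuple[str, ...] | list[str] | None = None,
    delta: float = 0.10,
    horizon: int = 10,
    control_dynamics: str = "static",
) -> list[TornadoEntry]:
    """Rerun the pipeline at ``x(1-delta)`` and ``x(1+delta)`` per parameter.

    Returns entries sorted by descending swing (tornado order).  A run whose
    incremental QALYs are non-positive yields a NaN ICER for that bar.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    names = tuple(parameter_list) if parameter_list is not None else DEFAULT_PARAMETERS
    unknown = [n for n in names if n not in _REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown parameter(s) {unknown}; valid names: {sorted(_REGISTRY)}"
        )

    def icer_of(s: Scenario) -> float:
        res = run_scenario(*s, horizon=horizon, control_dynamics=control_dynamics).cea
        return float("nan") if res.icer is None else res.icer

    baseline = icer_of(scenario)
    entries = []
    for name in names:
        perturb = _REGISTRY[name]
        lo = icer_of(perturb(scenario, 1.0 - delta))
        hi = icer_of(perturb(scenario, 1.0 + delta))
        swing = abs(hi - lo)
        entries.append(
            TornadoEntry(
                parameter_name=name,
                icer_low=lo,
                icer_high=hi,
                baseline_icer=baseline,
                swing=swing,
            )
        )
    entries.sort(key=lambda e: (not math.isnan(e.swing), e.swing), reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado table as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_name,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "baseline_icer": e.baseline_icer,
                "swing": e.swing,
            }
            for e in entries
        ]
    )
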