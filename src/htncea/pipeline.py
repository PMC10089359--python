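"""End-to-end scenario runner: decision tree -> Markov projection -> CEA."""

from __future__ import annotations

from dataclasses import dataclass

from .decision_tree import PhaseResult, run_implementation_phase
from .econ import CEAResult, EconParameters, compare_arms
from .markov import ProjectionTrace, run_projection
from .params import CohortProfile
from .risk import RiskParameters

__all__ = ["ScenarioRun", "run_scenario"]


@dataclass
class ScenarioRun:
    """All intermediate and final outputs of one full scenario evaluation."""

    profile: CohortProfile
    phase_factual: PhaseResult
    phase_counterfactual: PhaseResult
    trace_factual: ProjectionTrace
    trace_counterfactual: ProjectionTrace
    cea: CEAResult


def run_scenario(
    profile: CohortProfile,
    risk: RiskParameters,
    econ: EconParameters,
    horizon: int = 10,
    control_dynamics: str = "static",
) -> ScenarioRun:
    """Run both arms through the full pipeline and compare them."""
    phase_f = run_implementation_phase(profile, risk, "factual")
    phase_cf = run_implementation_phase(profile, risk, "counterfactual")
    trace_f = run_projection(phase_f, profile, risk, horizon, control_dynamics)
    trace_cf = run_projection(phase_cf, profile, risk, horizon, control_dynamics)
    cea = compare_arms((phase_f, trace_f), (phase_cf, trace_cf), econ)
    return ScenarioRun(
        profile=profile,
        phase_factual=phase_f,
        phase_counterfactual=phase_cf,
        trace_factual=trace_f,
        trace_counterfactual=trace_cf,
        cea=cea,
    )
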