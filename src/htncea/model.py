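"""Model/Results interface wrapping the full evaluation pipeline.

:class:`HypertensionCEModel` bundles a cohort profile, risk parameters, and
economic parameters; :meth:`~HypertensionCEModel.fit` evaluates the decision
tree and Markov projection for both arms and returns a :class:`CEResults`
object carrying every intermediate trace, the cost-effectiveness comparison,
a ``summary()`` table, and sensitivity analysis.

Example
-------
>>> from htncea import HypertensionCEModel
>>> res = HypertensionCEModel.from_preset("ulaanbaatar").fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .decision_tree import events_averted
from .econ import EconParameters
from .markov import cumulative_outcomes
from .params import CohortProfile, load_preset, load_scenario
from .pipeline import ScenarioRun, run_scenario
from .risk import RiskParameters
from .sensitivity import one_way_sensitivity, tornado_frame

__all__ = ["HypertensionCEModel", "CEResults"]


class HypertensionCEModel:
    """Cohort-level health-economic model of a hypertension-control program.

    Parameters
    ----------
    cohort, risk, econ
        The three validated parameter groups.
    horizon
        Projection length in annual Markov cycles (default 10).
    control_dynamics
        ``"static"`` (survivors keep their control status) or ``"rebalance"``
        (control fraction held exactly constant among survivors).
    """

    def __init__(
        self,
        cohort: CohortProfile,
        risk: RiskParameters,
        econ: EconParameters,
        horizon: int = 10,
        control_dynamics: str = "static",
    ):
        if risk.life_table is None:
            raise ValueError("risk parameters must carry a life table")
        self.cohort = cohort
        self.risk = risk
        self.econ = econ
        self.horizon = horizon
        self.control_dynamics = control_dynamics

    @classmethod
    def from_config(cls, source, **kwargs) -> "HypertensionCEModel":
        """Build from a YAML/JSON scenario document (path, text, or mapping)."""
        profile, risk, econ = load_scenario(source)
        return cls(profile, risk, econ, **kwargs)

    @classmethod
    def from_preset(cls, name: str, **kwargs) -> "HypertensionCEModel":
        """Build from a shipped city preset (see :func:`htncea.available_presets`)."""
        profile, risk, econ = load_preset(name)
        return cls(profile, risk, econ, **kwargs)

    def fit(self) -> "CEResults":
        """Evaluate both arms end to end and return the results object."""
        run = run_scenario(
            self.cohort,
            self.risk,
            self.econ,
            horizon=self.horizon,
            control_dynamics=self.control_dynamics,
        )
        return CEResults(self, run)


class CEResults:
    """Fitted results: traces, averted events, CEA, summary, sensitivity."""

    def __init__(self, model: HypertensionCEModel, run: ScenarioRun):
        self.model = model
        self.run = run
        self.cea = run.cea
        self.phase_factual = run.phase_factual
        self.phase_counterfactual = run.phase_counterfactual
        self.trace_factual = run.trace_factual
        self.trace_counterfactual = run.trace_counterfactual

    # ---------------------------------------------------------------- tables

    def phase_table(self) -> pd.DataFrame:
        """Implementation-phase block: totals and per-1,000, both arms."""
        av = events_averted(self.phase_counterfactual, self.phase_factual)
        rows = []
        for key, label in [("chd", "CHD"), ("stroke", "Stroke"), ("deaths", "Deaths")]:
            s = av[key]
            rows.append(
                {
                    "event_type": label,
                    "counterfactual": s.counterfactual,
                    "factual": s.factual,
                    "averted": s.averted,
                    "percent_averted": s.percent_averted,
                    "per_1000_counterfactual": s.per_1000_counterfactual,
                    "per_1000_factual": s.per_1000_factual,
                    "per_1000_averted": s.per_1000_averted,
                }
            )
        return pd.DataFrame(rows)

    def projection_table(self) -> pd.DataFrame:
        """Ten-year block: cumulative totals and per-1,000, both arms."""
        cum_cf = cumulative_outcomes(self.trace_counterfactual).iloc[-1]
        cum_f = cumulative_outcomes(self.trace_factual).iloc[-1]
        rows = []
        for key, label in [("chd", "CHD"), ("stroke", "Stroke"), ("deaths", "Deaths")]:
            cf = cum_cf[f"cum_{key}"]
            f = cum_f[f"cum_{key}"]
            rows.append(
                {
                    "event_type": label,
                    "counterfactual": cf,
                    "factual": f,
                    "averted": cf - f,
                    "percent_averted": 100.0 * (cf - f) / cf if cf > 0 else 0.0,
                    "per_1000_counterfactual": cum_cf[f"cum_{key}_per_1000"],
                    "per_1000_factual": cum_f[f"cum_{key}_per_1000"],
                    "per_1000_averted": cum_cf[f"cum_{key}_per_1000"]
                    - cum_f[f"cum_{key}_per_1000"],
                }
            )
        return pd.DataFrame(rows)

    def cea_table(self) -> pd.DataFrame:
        """Cost-effectiveness block mirroring the standard reporting layout."""
        econ = self.model.econ
        c = self.cea
        icer = round(c.icer) if c.icer is not None else "NA"
        rows = [
            ("Incremental cost (USD)", round(c.incremental_cost)),
            ("Incremental QALYs", round(c.incremental_qalys)),
            ("Incremental QALYs / 1,000 patients", round(c.incremental_qalys_per_1000)),
            ("ICER (USD per QALY gained)", icer),
            (
                "ICER threshold (USD per QALY gained)",
                f"{econ.icer_threshold_low:,.0f}-{econ.icer_threshold_high:,.0f}",
            ),
            ("GDP per capita (USD)", round(econ.gdp_per_capita)),
            ("WHO-CHOICE threshold (3x GDP, USD)", round(econ.who_choice_threshold)),
            ("Cost-effective (adjusted threshold)", c.cost_effective_adjusted),
            ("Cost-effective (WHO-CHOICE)", c.cost_effective_whochoice),
            (
                "Breakeven",
                f"Year {c.breakeven_year}" if c.breakeven_year is not None else "No",
            ),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def sensitivity(self, parameter_list=None, delta: float = 0.10) -> pd.DataFrame:
        """One-way tornado analysis around this model's parameters."""
        entries = one_way_sensitivity(
            (self.model.cohort, self.model.risk, self.model.econ),
            parameter_list=parameter_list,
            delta=delta,
            horizon=self.model.horizon,
            control_dynamics=self.model.control_dynamics,
        )
        return tornado_frame(entries)

    # --------------------------------------------------------------- exports

    def to_dict(self) -> dict:
        """Full-precision results as a JSON-serializable dictionary."""
        av_phase = events_averted(self.phase_counterfactual, self.phase_factual)
        return {
            "city": self.model.cohort.city_label,
            "n_patients": self.model.cohort.n_patients,
            "horizon": self.model.horizon,
            "control_dynamics": self.model.control_dynamics,
            "phase": {
                k: {
                    "counterfactual": s.counterfactual,
                    "factual": s.factual,
                    "averted": s.averted,
                    "percent_averted": s.percent_averted,
                }
                for k, s in av_phase.items()
            },
            "projection": self.projection_table().to_dict(orient="records"),
            "cea": self.cea.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        """Human-readable summary of the fitted model."""
        cohort = self.model.cohort
        lines = [
            f"Hypertension program cost-effectiveness — {cohort.city_label}",
            f"  cohort: n={cohort.n_patients:,}, mean age {cohort.mean_age:.0f}, "
            f"male fraction {cohort.male_fraction:.2f}",
            f"  control rate: {cohort.control_rate_baseline:.0%} (baseline) -> "
            f"{cohort.control_rate_end:.0%} (end of implementation)",
            "",
            "Implementation phase (2 years)",
            self.phase_table().round(1).to_string(index=False),
            "",
            f"Ten-year projection ({self.model.horizon} cycles, "
            f"{self.model.control_dynamics} control dynamics)",
            self.projection_table().round(1).to_string(index=False),
            "",
            "Cost-effectiveness",
            self.cea_table().to_string(index=False),
        ]
        return "\n".join(lines)
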