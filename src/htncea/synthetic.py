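"""Synthetic cohorts, parametric life tables, and a microsimulation oracle.

The primary patient data behind the shipped presets are confidential, so this
module generates everything the model pipeline consumes:

* patient-level cohorts with the summary structure the model expects (sex,
  CV-risk category, control status under each arm, age);
* Gompertz life tables standing in for national mortality data;
* a patient-level Monte-Carlo microsimulation that replays the cohort model's
  per-patient probabilities as independent annual Bernoulli draws, providing
  a first-principles check on the deterministic Markov projection.

All randomness flows through :func:`numpy.random.default_rng` seeded per
operation; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import PhaseResult
from .params import RISK_CATEGORIES, CohortProfile, LifeTable
from .risk import RiskParameters, cohort_state_rates, mortality_probs

__all__ = [
    "SyntheticPatient",
    "make_cohort",
    "make_life_table",
    "microsim_oracle",
    "MicrosimResult",
    "profile_from_patients",
    "phase_seed_from_patients",
]


@dataclass(frozen=True)
class SyntheticPatient:
    sex: str
    risk_category: str
    controlled_factual: bool
    controlled_counterfactual: bool
    age: float


def make_cohort(
    seed: int,
    n: int,
    male_fraction: float,
    risk_distribution: dict[str, float],
    control_baseline: float,
    control_end: float,
    mean_age: float,
    age_sd: float = 8.0,
    city_label: str = "synthetic",
    implementation_years: float = 2.0,
) -> tuple[CohortProfile, list[SyntheticPatient]]:
    """Sample a synthetic treated-hypertension cohort.

    The returned :class:`CohortProfile` summarizes the *sampled* patients
    (empirical frequencies and mean age), not the requested parameters, so
    downstream cohort arithmetic is exactly consistent with the patient list.

    Control status is comonotone across arms: a patient controlled under the
    baseline rate is also controlled under the (typically higher) end rate.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for name, p in [
        ("male_fraction", male_fraction),
        ("control_baseline", control_baseline),
        ("control_end", control_end),
    ]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    probs = np.array([risk_distribution[k] for k in RISK_CATEGORIES], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("risk_distribution must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n) < male_fraction, "male", "female")
    cats = rng.choice(np.array(RISK_CATEGORIES), size=n, p=probs)
    u_ctrl = rng.random(n)
    ctrl_cf = u_ctrl < control_baseline
    ctrl_f = u_ctrl < control_end
    ages = np.clip(rng.normal(mean_age, age_sd, size=n), 18.0, 100.0)

    patients = [
        SyntheticPatient(
            sex=str(sexes[i]),
            risk_category=str(cats[i]),
            controlled_factual=bool(ctrl_f[i]),
            controlled_counterfactual=bool(ctrl_cf[i]),
            age=float(ages[i]),
        )
        for i in range(n)
    ]
    profile = profile_from_patients(
        patients, city_label=city_label, implementation_years=implementation_years
    )
    return profile, patients


def profile_from_patients(
    patients: list[SyntheticPatient],
    city_label: str = "synthetic",
    implementation_years: float = 2.0,
) -> CohortProfile:
    """Empirical cohort summary of a patient list."""
    n = len(patients)
    if n == 0:
        raise ValueError("patient list is empty")
    n_male = sum(p.sex == "male" for p in patients)
    counts = {k: sum(p.risk_category == k for p in patients) for k in RISK_CATEGORIES}
    dist = {
        "low": counts["low"] / n,
        "medium": counts["medium"] / n,
        "high": 1.0 - counts["low"] / n - counts["medium"] / n,
    }
    return CohortProfile(
        city_label=city_label,
        n_patients=n,
        male_fraction=n_male / n,
        mean_age=float(np.mean([p.age for p in patients])),
        risk_distribution=dist,
        control_rate_baseline=sum(p.controlled_counterfactual for p in patients) / n,
        control_rate_end=sum(p.controlled_factual for p in patients) / n,
        implementation_years=implementation_years,
    )


def make_life_table(
    model: str = "gompertz",
    a: float = 5e-5,
    b: float = 0.09,
    age_range: tuple[int, int] = (18, 100),
) -> LifeTable:
    """Parametric life table: Gompertz hazard ``a * exp(b * age)``.

    Annual death probability is ``qx(age) = 1 - exp(-a * exp(b * age))``,
    capped at 1 — the standard adult-mortality law, adequate for tests and
    synthetic scenarios.
    """
    if model != "gompertz":
        raise ValueError(f"unknown life-table model {model!r}")
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    ages = np.arange(age_range[0], age_range[1] + 1)
    qx = np.minimum(1.0, 1.0 - np.exp(-a * np.exp(b * ages)))
    return LifeTable(ages, qx)


@dataclass
class MicrosimResult:
    """Per-replicate cumulative counts with Monte-Carlo means and SEs."""

    chd: np.ndarray
    stroke: np.ndarray
    deaths: np.ndarray

    @property
    def mean(self) -> dict[str, float]:
        return {
            "chd": float(self.chd.mean()),
            "stroke": float(self.stroke.mean()),
            "deaths": float(self.deaths.mean()),
        }

    @property
    def se(self) -> dict[str, float]:
        r = len(self.chd)
        return {
            "chd": float(self.chd.std(ddof=1) / np.sqrt(r)),
            "stroke": float(self.stroke.std(ddof=1) / np.sqrt(r)),
            "deaths": float(self.deaths.std(ddof=1) / np.sqrt(r)),
        }


def phase_seed_from_patients(
    patients: list[SyntheticPatient], arm: str, start_age: float | None = None
) -> PhaseResult:
    """Build a projection seed whose state counts match the patient list.

    Useful for validating the Markov projection directly against the
    microsimulation without running the decision tree first.
    """
    flag = "controlled_factual" if arm == "factual" else "controlled_counterfactual"
    n_ctrl = sum(getattr(p, flag) for p in patients)
    n = len(patients)
    if start_age is None:
        start_age = float(np.mean([p.age for p in patients]))
    return PhaseResult(
        arm_label=arm,
        chd_events=0.0,
        stroke_events=0.0,
        deaths=0.0,
        end_controlled=float(n_ctrl),
        end_uncontrolled=float(n - n_ctrl),
        end_age=start_age,
        person_years=0.0,
        uncontrolled_person_years=0.0,
    )


def microsim_oracle(
    patients: list[SyntheticPatient],
    risk: RiskParameters,
    horizon: int = 10,
    replicates: int = 500,
    seed: int = 0,
    arm: str = "factual",
    start_age: float | None = None,
) -> MicrosimResult:
    """Patient-level Monte-Carlo replay of the Markov projection.

    Each alive patient makes an annual Bernoulli event draw and an annual
    Bernoulli death draw with exactly the per-patient probabilities the
    cohort model assigns: the cohort-average per-state event probabilities
    (controlled vs uncontrolled) and the calibrated per-state death
    probabilities along the deterministic control-mix trajectory (static
    control dynamics — survivors keep their status).  Events are tolls;
    event type is a Bernoulli draw with the stroke fraction.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    flag = "controlled_factual" if arm == "factual" else "controlled_counterfactual"
    controlled = np.array([getattr(p, flag) for p in patients], dtype=bool)
    n = len(patients)
    profile = profile_from_patients(patients)
    if start_age is None:
        start_age = profile.mean_age
    p_unc, p_ctl = cohort_state_rates(profile, risk)
    p_event = np.where(controlled, p_ctl, p_unc)

    # per-state death probabilities: same baseline-mix-anchored calibration
    # as the cohort projection, so expectations coincide exactly
    u_ref = 1.0 - profile.control_rate_baseline
    q_pairs = [
        mortality_probs(
            start_age + t - 1,
            risk.life_table,
            risk.mortality_multiplier_uncontrolled,
            u_ref,
            mode=risk.mortality_mode,
        )
        for t in range(1, horizon + 1)
    ]

    rng = np.random.default_rng(seed)
    alive = np.ones((replicates, n), dtype=bool)
    chd = np.zeros(replicates)
    stroke = np.zeros(replicates)
    deaths = np.zeros(replicates)
    for q_c, q_u in q_pairs:
        q = np.where(controlled, q_c, q_u)
        events = (rng.random((replicates, n)) < p_event) & alive
        is_stroke = rng.random((replicates, n)) < risk.stroke_fraction
        stroke += (events & is_stroke).sum(axis=1)
        chd += (events & ~is_stroke).sum(axis=1)
        died = (rng.random((replicates, n)) < q) & alive
        deaths += died.sum(axis=1)
        alive &= ~died
    return MicrosimResult(chd=chd, stroke=stroke, deaths=deaths)
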