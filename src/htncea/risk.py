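"""Event- and mortality-risk machinery.

Annual cardiovascular event probabilities are derived from 10-year risks
(Framingham-style, supplied per sex and CV-risk category) under a
constant-hazard annualization, reduced for controlled patients by hazard
ratios stratified by sex and initial blood-pressure band.  A fixed fraction
of events are strokes, the remainder coronary heart disease (CHD) events.
Mortality comes from a national life table, differentiated by control status
through a multiplier for uncontrolled patients.
"""

from __future__ import annotations

import warnings

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import RISK_CATEGORIES, SEXES, CohortProfile, LifeTable

__all__ = [
    "RiskParameters",
    "annualize_risk",
    "cohort_annual_event_rate",
    "cohort_state_rates",
    "split_events",
    "mortality_probs",
]


class RiskParameters(BaseModel):
    """Event and mortality risk inputs.

    Parameters
    ----------
    ten_year_cvd_risk
        10-year probability of a CVD event for an *uncontrolled* patient,
        keyed by sex then risk category, e.g.
        ``{"male": {"low": 0.05, ...}, "female": {...}}``.
    hazard_ratio_controlled
        Multiplicative reduction in the annual event probability enjoyed by a
        controlled patient, keyed by sex then initial-BP band.
    band_mapping
        Maps a CV-risk category to the initial-BP band used for the
        hazard-ratio lookup (patient-level BP is unavailable in cohort mode).
        Defaults to the identity mapping.
    stroke_fraction
        Share of CVD events that are strokes; the rest are CHD events.
    mortality_multiplier_uncontrolled
        Relative risk of death for uncontrolled vs controlled patients.
    mortality_mode
        ``"calibrated"`` (default): controlled/uncontrolled death
        probabilities are scaled so their control-mix-weighted average equals
        the life-table value.  ``"direct"``: controlled patients die at the
        life-table rate and uncontrolled at multiplier times that rate.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, validate_assignment=True)

    ten_year_cvd_risk: dict[str, dict[str, float]]
    hazard_ratio_controlled: dict[str, dict[str, float]]
    band_mapping: dict[str, str] = Field(
        default_factory=lambda: {k: k for k in RISK_CATEGORIES}
    )
    stroke_fraction: float = Field(ge=0.0, le=1.0)
    mortality_multiplier_uncontrolled: float = Field(ge=1.0)
    mortality_mode: str = "calibrated"
    life_table: LifeTable | None = None

    @field_validator("ten_year_cvd_risk")
    @classmethod
    def _check_risks(cls, v):
        for sex in SEXES:
            if sex not in v:
                raise ValueError(f"ten_year_cvd_risk missing sex {sex!r}")
            for cat in RISK_CATEGORIES:
                if cat not in v[sex]:
                    raise ValueError(f"ten_year_cvd_risk[{sex!r}] missing category {cat!r}")
                r = v[sex][cat]
                if not 0.0 <= r < 1.0:
                    raise ValueError(f"10-year risk must be in [0, 1), got {r} for ({sex}, {cat})")
        return v

    @field_validator("hazard_ratio_controlled")
    @classmethod
    def _check_hrs(cls, v):
        for sex, bands in v.items():
            for band, hr in bands.items():
                if hr <= 0:
                    raise ValueError(f"hazard ratio must be positive, got {hr} for ({sex}, {band})")
        return v

    @field_validator("mortality_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("calibrated", "direct"):
            raise ValueError(f"mortality_mode must be 'calibrated' or 'direct', got {v!r}")
        return v

    def hazard_ratio(self, sex: str, category: str) -> float:
        band = self.band_mapping[category]
        return self.hazard_ratio_controlled[sex][band]


def annualize_risk(ten_year_risk: float) -> float:
    """Convert a 10-year event probability to an annual one.

    Uses the constant-hazard transform ``1 - (1 - r10)**(1/10)``, the standard
    convention for annual-cycle Markov models.
    """
    if not 0.0 <= ten_year_risk < 1.0:
        raise ValueError(f"10-year risk must be in [0, 1), got {ten_year_risk}")
    return 1.0 - (1.0 - ten_year_risk) ** 0.1


def cohort_state_rates(profile: CohortProfile, risk: RiskParameters) -> tuple[float, float]:
    """Cohort-average annual event probabilities by control state.

    Returns ``(p_uncontrolled, p_controlled)``: the sex-and-risk-category
    weighted mean annual event probability of an uncontrolled patient, and
    the corresponding mean with each stratum's hazard ratio applied.
    """
    sexfrac = profile.sex_fractions()
    weights = {
        (s, k): sexfrac[s] * profile.risk_distribution[k]
        for s in SEXES
        for k in RISK_CATEGORIES
    }
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stratum weights must sum to 1, got {total}")
    p_unc = sum(
        w * annualize_risk(risk.ten_year_cvd_risk[s][k]) for (s, k), w in weights.items()
    )
    p_ctl = sum(
        w * annualize_risk(risk.ten_year_cvd_risk[s][k]) * risk.hazard_ratio(s, k)
        for (s, k), w in weights.items()
    )
    return p_unc, p_ctl


def cohort_annual_event_rate(
    profile: CohortProfile, risk: RiskParameters, control_rate: float
) -> float:
    """Population-level annual CVD event probability at a given control rate.

    Mixes the uncontrolled and controlled per-state rates from
    :func:`cohort_state_rates` with weights ``1 - control_rate`` and
    ``control_rate``.
    """
    if not 0.0 <= control_rate <= 1.0:
        raise ValueError(f"control_rate must be in [0, 1], got {control_rate}")
    p_unc, p_ctl = cohort_state_rates(profile, risk)
    return (1.0 - control_rate) * p_unc + control_rate * p_ctl


def split_events(total_events: float, stroke_fraction: float) -> tuple[float, float]:
    """Split total CVD events into (CHD, stroke) counts by the stroke share."""
    if total_events < 0:
        raise ValueError("total_events must be non-negative")
    stroke = stroke_fraction * total_events
    chd = total_events - stroke
    return chd, stroke


def mortality_probs(
    age: float,
    life_table: LifeTable,
    multiplier: float,
    uncontrolled_share: float,
    mode: str = "calibrated",
) -> tuple[float, float]:
    """Annual death probabilities (controlled, uncontrolled) at ``age``.

    In ``calibrated`` mode the pair is scaled so the mix-weighted average
    ``(1-u)*q_c + u*q_u`` equals the life-table value q(a), anchoring
    all-cause deaths to national data: ``q_c = q(a) / (1 - u + k*u)`` and
    ``q_u = k * q_c``.  In ``direct`` mode ``q_c = q(a)`` and
    ``q_u = k * q(a)``.  Either probability is capped at 1 with a warning.
    """
    if not 0.0 <= uncontrolled_share <= 1.0:
        raise ValueError(f"uncontrolled_share must be in [0, 1], got {uncontrolled_share}")
    qa = life_table.lookup(age)
    if mode == "calibrated":
        q_c = qa / (1.0 - uncontrolled_share + multiplier * uncontrolled_share)
        q_u = multiplier * q_c
    elif mode == "direct":
        q_c = qa
        q_u = multiplier * qa
    else:
        raise ValueError(f"unknown mortality mode {mode!r}")
    if q_u > 1.0 or q_c > 1.0:
        warnings.warn(
            f"death probability capped at 1 (age {age}, multiplier {multiplier})",
            stacklevel=2,
        )
    return min(q_c, 1.0), min(q_u, 1.0)
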