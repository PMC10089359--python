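import hypothesis
import numpy as np
import pytest

from htncea import CohortProfile, LifeTable, RiskParameters

hypothesis.settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # read-only fixtures are safely shared across examples
    suppress_health_check=[hypothesis.HealthCheck.function_scoped_fixture],
)
hypothesis.settings.load_profile("ci")

UNIFORM_RISKS = {
    "male": {"low": 0.05, "medium": 0.15, "high": 0.30},
    "female": {"low": 0.03, "medium": 0.10, "high": 0.22},
}
UNIFORM_HRS = {
    "male": {"low": 0.8, "medium": 0.7, "high": 0.6},
    "female": {"low": 0.8, "medium": 0.7, "high": 0.6},
}


@pytest.fixture
def flat_life_table():
    """Constant 1% annual death probability over ages 18-100."""
    ages = np.arange(18, 101)
    return LifeTable(ages, np.full(len(ages), 0.01))


@pytest.fixture
def zero_life_table():
    ages = np.arange(18, 101)
    return LifeTable(ages, np.zeros(len(ages)))


@pytest.fixture
def simple_profile():
    return CohortProfile(
        city_label="testville",
        n_patients=1000,
        male_fraction=0.4,
        mean_age=60.0,
        risk_distribution={"low": 0.5, "medium": 0.3, "high": 0.2},
        control_rate_baseline=0.10,
        control_rate_end=0.25,
        implementation_years=2.0,
    )


@pytest.fixture
def simple_risk(flat_life_table):
    return RiskParameters(
        ten_year_cvd_risk=UNIFORM_RISKS,
        hazard_ratio_controlled=UNIFORM_HRS,
        stroke_fraction=0.3,
        mortality_multiplier_uncontrolled=3.0,
        life_table=flat_life_table,
    )


def make_single_stratum_profile(control_baseline=0.5, control_end=0.5, n=1000, age=60.0):
    """Cohort that is 100% male / high-risk, for hand-computable examples."""
    return CohortProfile(
        city_label="single-stratum",
        n_patients=n,
        male_fraction=1.0,
        mean_age=age,
        risk_distribution={"low": 0.0, "medium": 0.0, "high": 1.0},
        control_rate_baseline=control_baseline,
        control_rate_end=control_end,
        implementation_years=2.0,
    )


def make_risk(
    life_table,
    r10_high=0.2,
    hr_high=0.5,
    stroke_fraction=0.3,
    multiplier=3.0,
    mode="calibrated",
):
    return RiskParameters(
        ten_year_cvd_risk={
            "male": {"low": 0.0, "medium": 0.0, "high": r10_high},
            "female": {"low": 0.0, "medium": 0.0, "high": r10_high},
        },
        hazard_ratio_controlled={
            "male": {"low": 1.0, "medium": 1.0, "high": hr_high},
            "female": {"low": 1.0, "medium": 1.0, "high": hr_high},
        },
        stroke_fraction=stroke_fraction,
        mortality_multiplier_uncontrolled=multiplier,
        mortality_mode=mode,
        life_table=life_table,
    )
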