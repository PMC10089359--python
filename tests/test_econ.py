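"""Costing, QALYs, discounting, ICER computation, and threshold verdicts."""

import numpy as np
import pandas as pd
import pytest

from htncea import (
    EconParameters,
    LifeTable,
    PhaseResult,
    ProjectionTrace,
    arm_costs,
    arm_qalys,
    compare_arms,
    discount_factor,
    load_preset,
    ppp_convert,
    run_scenario,
    utility_for_age,
)

from conftest import make_risk, make_single_stratum_profile


def basic_econ(**overrides):
    fields = dict(
        annual_htn_cost=0.0,
        chd_event_cost=0.0,
        stroke_event_cost=0.0,
        productivity_loss_annual=0.0,
        program_cost_total=0.0,
        discount_rate=0.0,
        icer_threshold_low=1000,
        icer_threshold_high=5000,
        gdp_per_capita=5000,
    )
    fields.update(overrides)
    return EconParameters(**fields)


def empty_phase(controlled, uncontrolled, age=60.0, person_years=0.0, chd=0.0, stroke=0.0):
    return PhaseResult(
        arm_label="factual",
        chd_events=chd,
        stroke_events=stroke,
        deaths=0.0,
        end_controlled=controlled,
        end_uncontrolled=uncontrolled,
        end_age=age,
        person_years=person_years,
        uncontrolled_person_years=0.0,
    )


def make_trace(rows, entry=100.0, n=100.0):
    cols = [
        "cycle",
        "age",
        "controlled_start",
        "uncontrolled_start",
        "controlled",
        "uncontrolled",
        "dead_cumulative",
        "chd_events",
        "stroke_events",
        "deaths",
    ]
    return ProjectionTrace(
        arm_label="factual",
        records=pd.DataFrame(rows, columns=cols),
        entry_cohort=entry,
        cohort_n=n,
    )


class TestPPPConvert:
    @pytest.mark.parametrize(
        "cost, factor, expected",
        [
            (1522, 5.57, 273),
            (5864, 1.37, 4280),
            (1522, 1.37, 1111),
            (5864, 5.57, 1053),
            (191, 5.57, 34),
            (191, 1.37, 139),
            (153, 5.57, 27),
            (153, 1.37, 112),
            (42, 1.0, 42),
        ],
    )
    def test_published_cost_grid(self, cost, factor, expected):
        assert ppp_convert(cost, factor) == expected

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            ppp_convert(100, 0.0)


class TestDiscountFactor:
    def test_zero_rate(self):
        assert all(discount_factor(0.0, t) == 1.0 for t in range(1, 11))

    def test_hand_value(self):
        assert discount_factor(0.05, 2) == pytest.approx(1 / 1.05**2, abs=1e-12)

    def test_monotone_decreasing(self):
        factors = [discount_factor(0.03, t) for t in range(1, 11)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_cycle_zero_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, 0)


class TestUtilityLookup:
    @pytest.mark.parametrize("age, u", [(55, 0.84), (60, 0.82), (79, 0.78), (95, 0.74)])
    def test_band_values(self, age, u):
        econ = basic_econ()
        assert utility_for_age(age, econ.age_band_utilities) == u

    def test_clamp_below_with_warning(self):
        econ = basic_econ()
        with pytest.warns(UserWarning, match="clamped"):
            assert utility_for_age(45, econ.age_band_utilities) == 0.84

    def test_clamp_above(self):
        econ = basic_econ()
        assert utility_for_age(104, econ.age_band_utilities) == 0.74


class TestArmCosts:
    def test_direct_sum_state_costs(self):
        """100 alive for 1 undiscounted cycle at 10/patient-year -> 1000."""
        phase = empty_phase(50, 50)
        trace = make_trace([[1, 60, 50, 50, 50, 50, 0, 0, 0, 0]])
        econ = basic_econ(annual_htn_cost=10.0)
        assert arm_costs(phase, trace, econ, include_program=False) == pytest.approx(1000.0)

    def test_program_flag_adds_exactly_program_cost(self):
        phase = empty_phase(50, 50)
        trace = make_trace([[1, 60, 50, 50, 50, 50, 0, 0, 0, 0]])
        econ = basic_econ(annual_htn_cost=10.0, program_cost_total=777.0)
        on = arm_costs(phase, trace, econ, include_program=True)
        off = arm_costs(phase, trace, econ, include_program=False)
        assert on - off == pytest.approx(777.0)

    def test_event_costs(self):
        """10 CHD events at 1,522 each, nothing else -> 15,220."""
        phase = empty_phase(50, 50)
        trace = make_trace([[1, 60, 50, 50, 50, 50, 0, 10, 0, 0]])
        econ = basic_econ(chd_event_cost=1522.0)
        assert arm_costs(phase, trace, econ, include_program=False) == pytest.approx(15220.0)

    def test_productivity_accrues_to_uncontrolled_only(self):
        phase = empty_phase(50, 50)
        trace = make_trace([[1, 60, 70, 30, 70, 30, 0, 0, 0, 0]])
        econ = basic_econ(productivity_loss_annual=100.0)
        assert arm_costs(phase, trace, econ, include_program=False) == pytest.approx(3000.0)

    def test_discounting_reduces_costs(self, simple_profile, simple_risk):
        econ0 = basic_econ(annual_htn_cost=100.0)
        econ5 = basic_econ(annual_htn_cost=100.0, discount_rate=0.05)
        run = run_scenario(simple_profile, simple_risk, econ0)
        c0 = arm_costs(run.phase_factual, run.trace_factual, econ0, include_program=False)
        c5 = arm_costs(run.phase_factual, run.trace_factual, econ5, include_program=False)
        assert c5 < c0


class TestArmQalys:
    def test_utility_weighting(self):
        """100 alive at age 55 for one undiscounted cycle -> 84.0 QALYs."""
        phase = empty_phase(0, 0)
        trace = make_trace([[1, 55, 60, 40, 60, 40, 0, 0, 0, 0]])
        assert arm_qalys(phase, trace, basic_econ()) == pytest.approx(84.0)

    def test_stroke_disutility(self):
        phase = empty_phase(0, 0)
        trace = make_trace([[1, 55, 0, 0, 0, 0, 0, 0, 1, 0]])
        assert arm_qalys(phase, trace, basic_econ()) == pytest.approx(-0.048)

    def test_all_dead_zero(self):
        phase = empty_phase(0, 0)
        trace = make_trace([[1, 55, 0, 0, 0, 0, 100, 0, 0, 0]])
        assert arm_qalys(phase, trace, basic_econ()) == 0.0

    def test_discounting_reduces_qalys(self, simple_profile, simple_risk):
        econ0 = basic_econ()
        econ5 = basic_econ(discount_rate=0.05)
        run = run_scenario(simple_profile, simple_risk, econ0)
        q0 = arm_qalys(run.phase_factual, run.trace_factual, econ0)
        q5 = arm_qalys(run.phase_factual, run.trace_factual, econ5)
        assert q5 < q0


class TestCompareArms:
    def test_icer_identity(self, simple_profile, simple_risk):
        econ = basic_econ(
            annual_htn_cost=50.0, chd_event_cost=1000.0, stroke_event_cost=4000.0,
            productivity_loss_annual=100.0, program_cost_total=1e5, discount_rate=0.03,
        )
        cea = run_scenario(simple_profile, simple_risk, econ).cea
        assert cea.icer * cea.incremental_qalys == pytest.approx(cea.incremental_cost, rel=1e-12)

    def test_identical_arms_unclear(self, simple_risk):
        profile = make_single_stratum_profile(control_baseline=0.5, control_end=0.5)
        econ = basic_econ()
        with pytest.warns(UserWarning, match="ICER undefined"):
            cea = run_scenario(profile, simple_risk, econ).cea
        assert cea.incremental_cost == pytest.approx(0.0, abs=1e-9)
        assert cea.incremental_qalys == pytest.approx(0.0, abs=1e-9)
        assert cea.icer is None
        assert cea.cost_effective_adjusted == "unclear"

    def test_cost_saving_sign(self, simple_profile, simple_risk):
        """Free dominating program: more QALYs at negative incremental cost."""
        econ = basic_econ(chd_event_cost=1000.0, stroke_event_cost=4000.0)
        cea = run_scenario(simple_profile, simple_risk, econ).cea
        assert cea.incremental_qalys > 0
        assert cea.incremental_cost <= 0
        assert cea.breakeven_year is not None

    def test_verdict_bands(self, simple_profile, simple_risk):
        base = dict(
            annual_htn_cost=0.0, chd_event_cost=0.0, stroke_event_cost=0.0,
            productivity_loss_annual=0.0, discount_rate=0.0,
        )
        # scale program cost to steer the ICER into each verdict band
        def verdicts(program_cost):
            econ = basic_econ(program_cost_total=program_cost, **base)
            cea = run_scenario(simple_profile, simple_risk, econ).cea
            return cea

        qalys = verdicts(0.0).incremental_qalys
        low, high = 1000, 5000
        assert verdicts(0.5 * low * qalys).cost_effective_adjusted == "yes"
        assert verdicts(2 * low * qalys).cost_effective_adjusted == "unclear"
        assert verdicts(2 * high * qalys).cost_effective_adjusted == "no"

    def test_who_choice_threshold_is_three_gdp(self):
        _, _, econ = load_preset("dakar")
        assert econ.who_choice_threshold == 3 * 1458 == 4374
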