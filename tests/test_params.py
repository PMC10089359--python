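"""Configuration loading, validation, presets, and life tables."""

import numpy as np
import pydantic
import pytest

from htncea import (
    LifeTable,
    available_presets,
    extrapolate_cohort,
    load_life_table,
    load_preset,
    load_scenario,
    save_scenario,
)


class TestPresets:
    def test_ulaanbaatar_cohort_values(self):
        profile, risk, econ = load_preset("ulaanbaatar")
        assert profile.n_patients == 10075
        assert profile.control_rate_baseline == 0.03
        assert profile.control_rate_end == 0.19
        assert profile.male_fraction == 0.37
        assert profile.mean_age == 61

    def test_sao_paulo_cohort_values(self):
        profile, _, _ = load_preset("sao_paulo")
        assert profile.n_patients == 5844
        assert profile.control_rate_end == 0.31
        assert profile.control_rate_baseline == 0.12

    def test_dakar_variants(self):
        main_profile, _, _ = load_preset("dakar")
        alt_profile, _, _ = load_preset("dakar_alt")
        assert main_profile.control_rate_baseline == 0.13
        assert alt_profile.control_rate_baseline == 0.07
        assert main_profile.n_patients == alt_profile.n_patients == 5236

    @pytest.mark.parametrize(
        "preset, htn, chd, stroke, productivity, program, ppp",
        [
            ("ulaanbaatar", 34, 273, 1053, 27, 663771, 5.57),
            ("dakar", 139, 1111, 4280, 112, 428927, 1.37),
            ("sao_paulo", 191, 1522, 5864, 153, 591229, 1.0),
        ],
    )
    def test_cost_assumptions(self, preset, htn, chd, stroke, productivity, program, ppp):
        _, _, econ = load_preset(preset)
        assert econ.annual_htn_cost == htn
        assert econ.chd_event_cost == chd
        assert econ.stroke_event_cost == stroke
        assert econ.productivity_loss_annual == productivity
        assert econ.program_cost_total == program
        assert econ.ppp_factor == ppp

    @pytest.mark.parametrize(
        "preset, low, high, gdp, discount",
        [
            ("ulaanbaatar", 1624, 4849, 4135, 0.03),
            ("dakar", 73, 1166, 1458, 0.03),
            ("sao_paulo", 3210, 10122, 9151, 0.05),
        ],
    )
    def test_thresholds_and_discounting(self, preset, low, high, gdp, discount):
        _, _, econ = load_preset(preset)
        assert econ.icer_threshold_low == low
        assert econ.icer_threshold_high == high
        assert econ.gdp_per_capita == gdp
        assert econ.discount_rate == discount

    def test_utility_assumptions(self):
        for preset in available_presets():
            _, _, econ = load_preset(preset)
            assert econ.age_band_utilities == {
                "50-59": 0.84,
                "60-69": 0.82,
                "70-79": 0.78,
                "80-100": 0.74,
            }
            assert econ.event_disutility == {"chd": 0.018, "stroke": 0.048}

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            load_preset("atlantis")


class TestLoadScenario:
    def test_missing_field_names_it(self):
        doc = load_preset_doc()
        del doc["cohort"]["n_patients"]
        with pytest.raises(pydantic.ValidationError, match="n_patients"):
            load_scenario(doc)

    def test_missing_section(self):
        doc = load_preset_doc()
        del doc["economics"]
        with pytest.raises(ValueError, match="economics"):
            load_scenario(doc)

    def test_out_of_range_value(self):
        doc = load_preset_doc()
        doc["cohort"]["control_rate_end"] = 1.4
        with pytest.raises(pydantic.ValidationError, match="control_rate_end"):
            load_scenario(doc)

    def test_unknown_key_warns_not_errors(self):
        doc = load_preset_doc()
        doc["cohort"]["favourite_colour"] = "blue"
        with pytest.warns(UserWarning, match="favourite_colour"):
            profile, _, _ = load_scenario(doc)
        assert profile.n_patients == 10075

    def test_risk_distribution_must_sum_to_one(self):
        doc = load_preset_doc()
        doc["cohort"]["risk_distribution"] = {"low": 0.5, "medium": 0.4, "high": 0.2}
        with pytest.raises(pydantic.ValidationError, match="sum to 1"):
            load_scenario(doc)

    def test_round_trip(self, tmp_path):
        profile, risk, econ = load_preset("ulaanbaatar")
        out = tmp_path / "scenario.yaml"
        save_scenario(profile, risk, econ, out)
        profile2, risk2, econ2 = load_scenario(out)
        assert profile2 == profile
        assert econ2 == econ
        assert risk2.ten_year_cvd_risk == risk.ten_year_cvd_risk
        assert risk2.life_table == risk.life_table


class TestLifeTable:
    def test_read_back(self, tmp_path):
        f = tmp_path / "lt.csv"
        f.write_text("age,qx\n60,0.01\n61,0.011\n")
        lt = load_life_table(f)
        assert lt.lookup(60) == 0.01
        assert lt.lookup(61) == 0.011

    def test_lookup_clamps_to_range(self, tmp_path):
        f = tmp_path / "lt.csv"
        f.write_text("age,qx\n60,0.01\n61,0.011\n")
        lt = load_life_table(f)
        assert lt.lookup(120) == 0.011
        assert lt.lookup(30) == 0.01

    def test_qx_out_of_range(self, tmp_path):
        f = tmp_path / "lt.csv"
        f.write_text("age,qx\n60,0.01\n61,1.5\n")
        with pytest.raises(ValueError, match="outside"):
            load_life_table(f)

    def test_non_monotone_ages(self):
        with pytest.raises(ValueError, match="increasing"):
            LifeTable([60, 59], [0.01, 0.01])

    def test_gap_in_ages(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable([60, 62], [0.01, 0.01])


class TestExtrapolateCohort:
    @pytest.mark.parametrize(
        "sampled, centers_sampled, centers_total, expected",
        [(1461, 6, 24, 5844), (100, 5, 5, 100), (7, 3, 24, 56)],
    )
    def test_values(self, sampled, centers_sampled, centers_total, expected):
        assert extrapolate_cohort(sampled, centers_sampled, centers_total) == expected

    def test_zero_centers_sampled(self):
        with pytest.raises(ValueError):
            extrapolate_cohort(100, 0, 24)

    def test_sampled_exceeds_total(self):
        with pytest.raises(ValueError):
            extrapolate_cohort(100, 25, 24)


def load_preset_doc():
    """Ulaanbaatar preset as a raw mutable document for corruption tests."""
    import yaml
    from importlib import resources

    files = resources.files("htncea") / "presets"
    doc = yaml.safe_load((files / "ulaanbaatar.yaml").read_text())
    import htncea.params as params_mod
    from importlib.resources import as_file

    with as_file(files / doc["life_table_path"]) as p:
        doc["life_table_path"] = str(p)
    return doc
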