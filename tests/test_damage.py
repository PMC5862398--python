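"""Attributable risk, monetization, VSL schedules, and household damages."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airineq import (
    BELL_O3,
    KREWSKI_PM25,
    LEPEULE_PM25,
    VSLSchedule,
    adjust_vsl_income,
    adjusted_income_table,
    attributable_risk,
    beta_from_relative_risk,
    household_damage,
    monetize_person,
)
from airineq.damage import ConcentrationResponse


class TestAttributableRisk:
    def test_zero_slope_zero_risk(self):
        assert attributable_risk(0.01, 0.0, 50.0) == 0.0

    def test_half_risk_at_log_two(self):
        # beta * C = ln 2 halves the survival factor: M = gamma / 2
        assert attributable_risk(0.008, math.log(2), 1.0) == pytest.approx(0.004)

    def test_reference_evaluation(self):
        m = attributable_risk(0.01, 0.0058, 10.0)
        assert m == pytest.approx(5.635e-4, rel=1e-3)
        assert m == pytest.approx(0.01 * (1 - math.exp(-0.058)), rel=1e-14)

    def test_bounded_by_gamma_and_saturates(self):
        gamma = 0.02
        m = attributable_risk(gamma, 0.0058, 1e3)
        assert m < gamma
        # at extreme exposure the float saturates onto gamma from below
        m_inf = attributable_risk(gamma, 0.0058, 1e6)
        assert m_inf <= gamma
        assert m_inf == pytest.approx(gamma, rel=1e-9)

    def test_small_exposure_linearization(self):
        gamma, beta, c = 0.01, 1e-5, 10.0  # beta*C = 1e-4
        m = attributable_risk(gamma, beta, c)
        assert abs(m - gamma * beta * c) / m < 1e-3

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        gamma=st.floats(1e-6, 0.5),
        beta=st.floats(0.0, 0.05),
        conc=st.floats(0.0, 500.0),
    )
    # beta*C capped at 25: beyond ~37 the survival factor e^(-beta*C)
    # underflows and M saturates onto gamma in float64
    def test_risk_in_range(self, gamma, beta, conc):
        m = attributable_risk(gamma, beta, conc)
        assert 0.0 <= m < gamma

    def test_monotone_in_each_argument(self):
        base = attributable_risk(0.01, 0.005, 10.0)
        assert attributable_risk(0.02, 0.005, 10.0) > base
        assert attributable_risk(0.01, 0.006, 10.0) > base
        assert attributable_risk(0.01, 0.005, 12.0) > base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            attributable_risk(0.0, 0.005, 10.0)
        with pytest.raises(ValueError):
            attributable_risk(0.01, -0.1, 10.0)
        with pytest.raises(ValueError):
            attributable_risk(0.01, 0.005, -1.0)


class TestMonetization:
    def test_zero_risk_zero_damage(self):
        assert monetize_person({"PM25": 0.0, "O3": 0.0}, 1e7) == 0.0

    def test_additive_over_pollutants(self):
        assert monetize_person({"PM25": 1e-4, "O3": 5e-5}, 1e7) == pytest.approx(1500.0)

    def test_linear_in_vsl(self):
        risks = {"PM25": 2e-4, "O3": 1e-4}
        assert monetize_person(risks, 2e7) == pytest.approx(
            2 * monetize_person(risks, 1e7)
        )

    def test_vsl_income_adjustment(self):
        assert adjust_vsl_income(1e7, 0.4, 50_000, 50_000) == 1e7
        assert adjust_vsl_income(1e7, 0.4, 100_000, 50_000) == pytest.approx(
            1e7 * 2**0.4
        )
        assert adjust_vsl_income(1e7, 0.0, 123.0, 50_000) == 1e7
        # non-positive income falls back to the base VSL
        assert adjust_vsl_income(1e7, 0.4, -5_000, 50_000) == 1e7

    def test_vsl_schedule_eta_zero_equals_uniform(self):
        uni = VSLSchedule(mode="uniform")
        varying = VSLSchedule(
            mode="income_varying", income_elasticity=0.0, reference_income=60_000
        )
        incomes = np.array([1e3, 5e4, 2e6])
        assert np.array_equal(uni.vsl_for(incomes), varying.vsl_for(incomes))

    def test_beta_from_relative_risk(self):
        assert beta_from_relative_risk(1.06, 10.0) == pytest.approx(
            math.log(1.06) / 10
        )
        assert KREWSKI_PM25.beta == pytest.approx(0.00583, abs=2e-5)
        assert LEPEULE_PM25.beta > KREWSKI_PM25.beta
        assert BELL_O3.beta == pytest.approx(0.000519, abs=2e-6)
        with pytest.raises(ValueError):
            beta_from_relative_risk(0.98, 10.0)


def _fixture_inputs(cohorts="8", income=5000.0, n_members=None):
    """One county, gamma=0.01 for cohort 8, C_PM=10, C_O3=28."""
    if n_members:
        cohorts = "|".join(["8"] * n_members)
    hh = pd.DataFrame(
        {
            "household_id": ["H1"],
            "year": [2011],
            "state_id": ["S0"],
            "county_id": ["C0"],
            "market_income": [income],
            "member_age_cohorts": [cohorts],
            "race": ["white"],
            "census_division": ["pacific"],
        }
    )
    mort = pd.DataFrame(
        {
            "county_id": ["C0"] * 2,
            "age_cohort": [8, 9],
            "rate": [0.01, 0.02],
            "death_count": [100, 100],
        }
    )
    conc = pd.DataFrame(
        {
            "county_id": ["C0", "C0"],
            "pollutant": ["PM25", "O3"],
            "concentration": [10.0, 28.0],
        }
    )
    return hh, mort, conc


FIXTURE_CRS = {
    "PM25": ConcentrationResponse("PM25", 0.0058, "fixture"),
    "O3": ConcentrationResponse("O3", 0.0005, "fixture"),
}


class TestHouseholdDamage:
    def test_reference_household(self):
        """gamma=0.01, beta_PM=0.0058, C_PM=10, beta_O3=0.0005, C_O3=28,
        VSL=$10.2M -> D ~ 7,166 USD, independently evaluated."""
        hh, mort, conc = _fixture_inputs()
        out = household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        expected = 1.02e7 * (
            0.01 * (1 - math.exp(-0.058)) + 0.01 * (1 - math.exp(-0.014))
        )
        assert out["damage"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert out["damage"].iloc[0] == pytest.approx(7166, abs=1.0)
        assert out["adjusted_income"].iloc[0] == pytest.approx(5000 - expected)

    def test_zero_concentration_zero_damage(self):
        hh, mort, conc = _fixture_inputs()
        conc["concentration"] = 0.0
        out = household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        assert out["damage"].iloc[0] == 0.0
        assert out["adjusted_income"].iloc[0] == out["market_income"].iloc[0]

    def test_two_identical_members_double_damage(self):
        hh1, mort, conc = _fixture_inputs(n_members=1)
        hh2, _, _ = _fixture_inputs(n_members=2)
        d1 = household_damage(hh1, mort, conc, FIXTURE_CRS, VSLSchedule())
        d2 = household_damage(hh2, mort, conc, FIXTURE_CRS, VSLSchedule())
        assert d2["damage"].iloc[0] == pytest.approx(2 * d1["damage"].iloc[0])

    def test_higher_cohort_weakly_higher_risk(self):
        """Holding the county fixed, an older-cohort member is damaged more."""
        hh8, mort, conc = _fixture_inputs(cohorts="8")
        hh9, _, _ = _fixture_inputs(cohorts="9")
        d8 = household_damage(hh8, mort, conc, FIXTURE_CRS, VSLSchedule())
        d9 = household_damage(hh9, mort, conc, FIXTURE_CRS, VSLSchedule())
        assert d9["damage"].iloc[0] > d8["damage"].iloc[0]

    def test_missing_mortality_cell_excludes_household(self):
        hh, mort, conc = _fixture_inputs(cohorts="8|12")  # cohort 12 missing
        out = household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        assert out.empty
        assert out.attrs["exclusions"]["missing_mortality_cell"] == 1

    def test_unmonitored_county_excludes_household(self):
        hh, mort, conc = _fixture_inputs()
        conc = conc[conc["pollutant"] == "O3"]  # no PM2.5 monitor
        out = household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        assert out.empty
        assert out.attrs["exclusions"]["unmonitored_county"] == 1

    def test_per_pollutant_damages_sum_to_total(self, small_prepared):
        hh, mort, conc = small_prepared
        out = household_damage(
            hh, mort, conc, {"PM25": KREWSKI_PM25, "O3": BELL_O3}, VSLSchedule()
        )
        assert np.allclose(
            out["damage"], out["damage_PM25"] + out["damage_O3"], rtol=1e-12
        )
        assert (out["damage"] >= 0).all()


class TestAdjustedIncomeTable:
    def test_subtraction_can_go_negative(self):
        hh, mort, conc = _fixture_inputs(income=5000.0)
        out = adjusted_income_table(
            household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        )
        assert out["adjusted_income"].iloc[0] == pytest.approx(-2166, abs=1.0)
        assert out.attrs["share_negative_adjusted"] == 1.0

    def test_zero_damage_identity(self):
        hh, mort, conc = _fixture_inputs()
        conc["concentration"] = 0.0
        out = adjusted_income_table(
            household_damage(hh, mort, conc, FIXTURE_CRS, VSLSchedule())
        )
        assert (out["adjusted_income"] == out["market_income"]).all()
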