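import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cstdkit import (
    ChemicalParams,
    ExposureScenario,
    IntakeSeries,
    StaticBody,
    concentration_static,
    concentration_static_from_intake,
    exposure_multiplier,
    static_cstd,
)
from cstdkit.exposure import DAYS_PER_YEAR, LN2
from cstdkit.trend_analysis import fit_loglinear

BODY = StaticBody()
SCEN = ExposureScenario(ban_year=1970.0, t_double_in=7.0, t_half_in=7.0, peak_intake=1.0)


def uptake(chem):
    return chem.absorbed_fraction * DAYS_PER_YEAR * BODY.body_weight / BODY.lipid_mass


class TestClosedForm:
    def test_pure_decay_from_initial_value(self):
        chem = ChemicalParams(5.0)
        null = ExposureScenario(1970.0, 7.0, 7.0, peak_intake=0.0)
        c = concentration_static(BODY, chem, null, 1980.0, 1990.0, c_birth=4.0)
        assert c == pytest.approx(4.0 * np.exp(-chem.k_elim * 10.0), rel=1e-12)

    def test_steady_state_under_constant_intake(self):
        # near-constant intake (enormous doubling time), long life -> u*E/k
        chem = ChemicalParams(2.0)
        s = ExposureScenario(1970.0, 1e9, 1e9, peak_intake=1.0)
        c = concentration_static(BODY, chem, s, 1800.0, 1960.0)
        assert c == pytest.approx(uptake(chem) * 1.0 / chem.k_elim, rel=1e-6)

    @pytest.mark.parametrize("t_half_elim", [0.7, 3.0, 14.0])
    @pytest.mark.parametrize("birth", [1950.0, 1975.0])
    def test_matches_numeric_ode_integration(self, t_half_elim, birth):
        """Closed form vs high-accuracy ODE solve across the ban year."""
        chem = ChemicalParams(t_half_elim)
        u = uptake(chem)

        def rhs(t, c):
            return [u * exposure_multiplier(SCEN, t) - chem.k_elim * c[0]]

        sol = solve_ivp(rhs, (birth, birth + 50.0), [0.0], rtol=1e-11, atol=1e-13,
                        dense_output=True)
        for ts in np.linspace(birth + 2.0, birth + 50.0, 10):
            c = concentration_static(BODY, chem, SCEN, birth, ts)
            assert c == pytest.approx(float(sol.sol(ts)[0]), rel=1e-4)

    def test_degenerate_elimination_equal_to_intake_decline(self):
        """k_elim == k_in is the removable singularity of the closed form."""
        chem_eq = ChemicalParams(SCEN.t_half_in)
        c_eq = concentration_static(BODY, chem_eq, SCEN, 1975.0, 2000.0)
        c_lo = concentration_static(BODY, ChemicalParams(SCEN.t_half_in * (1 - 1e-7)),
                                    SCEN, 1975.0, 2000.0)
        c_hi = concentration_static(BODY, ChemicalParams(SCEN.t_half_in * (1 + 1e-7)),
                                    SCEN, 1975.0, 2000.0)
        assert np.isfinite(c_eq)
        assert min(c_lo, c_hi) <= c_eq <= max(c_lo, c_hi)

    def test_whole_life_post_ban_matches_stated_closed_form(self):
        chem = ChemicalParams(14.0)
        k, kin, u = chem.k_elim, SCEN.k_fall, uptake(chem)
        ts, age = 2020.0, 30.0
        expected = (u * exposure_multiplier(SCEN, ts) / (k - kin)) * (
            1 - np.exp(-(k - kin) * age)
        )
        assert concentration_static(BODY, chem, SCEN, ts - age, ts) == pytest.approx(
            expected, rel=1e-12
        )

    def test_sampling_before_birth_rejected(self):
        with pytest.raises(ValueError):
            concentration_static(BODY, ChemicalParams(3.0), SCEN, 2000.0, 1990.0)


class TestTabulatedIntake:
    def test_matches_parametric_form_on_aligned_yearly_grid(self):
        """A yearly table containing the ban year reproduces the parametric
        piecewise-exponential trend exactly."""
        chem = ChemicalParams(6.0)
        years = np.arange(1900.0, 2051.0)
        table = IntakeSeries(years, SCEN.peak_intake * exposure_multiplier(SCEN, years))
        for birth, ts in [(1950.0, 1990.0), (1975.0, 2010.0), (1960.0, 1968.0)]:
            c_tab = concentration_static_from_intake(BODY, chem, table, birth, ts)
            c_par = concentration_static(BODY, chem, SCEN, birth, ts)
            assert c_tab == pytest.approx(c_par, rel=1e-10)

    def test_extrapolation_warns(self):
        chem = ChemicalParams(6.0)
        table = IntakeSeries([1990.0, 2000.0], [2.0, 1.0])
        with pytest.warns(UserWarning, match="extrapolated"):
            concentration_static_from_intake(BODY, chem, table, 1970.0, 2005.0)


class TestStaticCstd:
    def test_post_ban_concentration_ratio_independent_of_elimination(self):
        """Whole-life post-ban: C(ts+d)/C(ts) = 2^(-d/t_half_in) exactly,
        whatever the elimination half-life."""
        for t_elim in (0.5, 3.0, 14.0, 50.0):
            s = static_cstd(BODY, ChemicalParams(t_elim), SCEN, 30.0, [2010.0, 2024.0])
            assert s.concentration[1] / s.concentration[0] == pytest.approx(
                2.0 ** (-14.0 / 7.0), rel=1e-12
            )

    def test_cross_sectional_slope_theorem_machine_precision(self):
        years = np.arange(2005.0, 2081.0, 5.0)
        s = static_cstd(BODY, ChemicalParams(14.0), SCEN, 30.0, years)
        slopes = np.diff(np.log(s.concentration)) / np.diff(s.year)
        np.testing.assert_allclose(slopes, -LN2 / 7.0, rtol=1e-12)

    def test_pre_ban_doubling_time_equals_intake_doubling_time(self):
        years = np.arange(1930.0, 1961.0, 5.0)
        s = static_cstd(BODY, ChemicalParams(3.0), SCEN, 30.0, years)
        fit = fit_loglinear(s)
        assert fit.kind == "doubling"
        assert fit.half_life_or_doubling == pytest.approx(7.0, rel=1e-6)

    def test_slow_chemical_post_ban_halving_time_is_seven_years(self):
        years = np.arange(2005.0, 2081.0, 5.0)
        s = static_cstd(BODY, ChemicalParams(14.0), SCEN, 30.0, years)
        fit = fit_loglinear(s)
        assert fit.kind == "halving"
        assert fit.half_life_or_doubling == pytest.approx(7.0, rel=1e-9)
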