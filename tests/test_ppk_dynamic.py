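import numpy as np
import pytest
from scipy.integrate import quad

from cstdkit import (
    ChemicalParams,
    CoverageError,
    ExposureScenario,
    GrowthModel,
    ReproductionSchedule,
    SimulationFeatures,
    StaticBody,
    build_lineage,
    concentration_static,
    exposure_multiplier,
    extract_cstd,
    simulate_cstd,
    simulate_lineage,
)
from cstdkit.exposure import DAYS_PER_YEAR
from cstdkit.trend_analysis import fit_loglinear

SCEN = ExposureScenario(ban_year=1970.0, t_double_in=7.0, t_half_in=7.0, peak_intake=1.0)
ALL_OFF = SimulationFeatures(in_utero=False, breastfeeding=False, growth=False)


class TestSimulateLineage:
    def test_zero_intake_gives_zero_burden_everywhere(self):
        lin = build_lineage(1950.0, 3)
        null = ExposureScenario(1970.0, 7.0, 7.0, peak_intake=0.0)
        trajs = simulate_lineage(lin, ChemicalParams(3.0), null, (1950.0, 2040.0))
        for tr in trajs:
            assert np.all(tr.burden == 0.0)

    def test_mass_conservation_without_elimination(self):
        """k_elim = 0, transfer off, constant body: final burden equals the
        cumulative absorbed intake (independent quadrature oracle)."""
        chem = ChemicalParams(t_half_elim=np.inf)  # k_elim = 0
        lin = build_lineage(1950.0, 1)
        trajs = simulate_lineage(lin, chem, SCEN, (1950.0, 2000.0), features=ALL_OFF)
        bw = lin.members[0].growth.adult_body_weight

        def intake_ng_per_year(t):
            return SCEN.peak_intake * exposure_multiplier(SCEN, t) * bw * DAYS_PER_YEAR

        expected, _ = quad(intake_ng_per_year, 1950.0, 2000.0, points=[1970.0], limit=200)
        assert trajs[0].burden[-1] == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("t_half_elim", [3.0, 14.0])
    def test_static_limit_reproduces_closed_form(self, t_half_elim):
        """All dynamic features off -> the static model, to <0.1%."""
        chem = ChemicalParams(t_half_elim)
        growth = GrowthModel()
        body = StaticBody(growth.adult_body_weight, growth.adult_lipid_fraction)
        years = [1960.0, 1975.0, 1990.0, 2010.0, 2030.0]
        dyn = simulate_cstd(chem, SCEN, 30.0, years, features=ALL_OFF)
        ref = np.array(
            [concentration_static(body, chem, SCEN, y - 30.0, y) for y in years]
        )
        np.testing.assert_allclose(dyn.concentration, ref, rtol=1e-3)

    def test_longer_elimination_half_life_never_lowers_concentration(self):
        years = [1960.0, 1970.0, 1990.0, 2010.0, 2040.0]
        series = [
            simulate_cstd(ChemicalParams(t), SCEN, 30.0, years).concentration
            for t in (2.0, 3.0, 6.0, 14.0)
        ]
        for lo, hi in zip(series, series[1:]):
            assert np.all(hi >= lo * (1 - 1e-9))

    def test_non_finite_state_raises_integration_error(self):
        from cstdkit.errors import IntegrationError
        from cstdkit.ppk_dynamic import _simulate_individual

        lin = build_lineage(1950.0, 1)
        huge = ExposureScenario(1970.0, 7.0, 7.0, peak_intake=1e308)
        with pytest.raises((IntegrationError, OverflowError)):
            _simulate_individual(
                lin.members[0], None, False, ChemicalParams(3.0), huge, 2300.0,
                SimulationFeatures(), 1 / 52,
            )


class TestBreastfeedingTransfer:
    def setup_method(self):
        self.chem = ChemicalParams(t_half_elim=np.inf, absorbed_fraction=1.0)
        self.lin = build_lineage(1950.0, 2)
        self.window = (1950.0, 1990.0)
        self.on = simulate_lineage(
            self.lin, self.chem, SCEN, self.window,
            features=SimulationFeatures(in_utero=False, breastfeeding=True, growth=True),
        )
        self.off = simulate_lineage(
            self.lin, self.chem, SCEN, self.window,
            features=SimulationFeatures(in_utero=False, breastfeeding=False, growth=True),
        )

    def test_mother_burden_dips_during_lactation(self):
        mother_on, mother_off = self.on[0], self.off[0]
        weaning = 1980.0 + 0.5
        assert mother_on.burden_at(weaning) < mother_off.burden_at(weaning)

    def test_child_burden_at_weaning_exceeds_counterfactual(self):
        assert self.on[1].burden_at(1980.5) > self.off[1].burden_at(1980.5)

    def test_transfer_conserves_total_chemical(self):
        """With no elimination and full absorption, breastfeeding only moves
        chemical between mother and child."""
        t = 1985.0
        total_on = self.on[0].burden_at(t) + self.on[1].burden_at(t)
        total_off = self.off[0].burden_at(t) + self.off[1].burden_at(t)
        assert total_on == pytest.approx(total_off, rel=1e-4)

    def test_in_utero_transfer_sets_newborn_to_mothers_concentration(self):
        feats = SimulationFeatures(in_utero=True, breastfeeding=False, growth=True)
        trajs = simulate_lineage(self.lin, ChemicalParams(14.0),
                                 SCEN, self.window, features=feats)
        mother, child = trajs
        assert child.concentration[0] == pytest.approx(
            mother.concentration_at(child.birth_year), rel=1e-9
        )


class TestExtractCstd:
    def test_series_length_matches_request(self, fast_chem, scenario):
        years = np.arange(1996.0, 2011.0)  # 15 years
        s = simulate_cstd(fast_chem, scenario, 30.0, years)
        assert len(s) == 15

    def test_deterministic_repeat(self, fast_chem, scenario):
        years = [2000.0, 2005.0]
        a = simulate_cstd(fast_chem, scenario, 30.0, years)
        b = simulate_cstd(fast_chem, scenario, 30.0, years)
        np.testing.assert_array_equal(a.concentration, b.concentration)

    def test_missing_exact_age_raises_unless_nearest_enabled(self):
        lin = build_lineage(1950.0, 2)
        trajs = simulate_lineage(lin, ChemicalParams(3.0), SCEN, (1950.0, 2000.0))
        with pytest.raises(CoverageError, match="nearest"):
            extract_cstd(trajs, 30.0, [1995.0])
        s = extract_cstd(trajs, 30.0, [1995.0], nearest=True)
        assert s.age[0] != 30.0

    def test_pre_ban_log_slope_matches_intake_doubling(self, cstd_fast_pre):
        fit = fit_loglinear(cstd_fast_pre)
        assert fit.kind == "doubling"
        assert fit.slope == pytest.approx(np.log(2) / 7.0, rel=1e-6)


class TestSlowEliminatorShape:
    def test_slow_post_ban_decline_slower_than_fast(self, cstd_fast_post, cstd_slow_post):
        """Under one intake trend, the slowly eliminated chemical's post-ban
        CSTD halving time exceeds the rapidly eliminated one's."""
        t_fast = fit_loglinear(cstd_fast_post).half_life_or_doubling
        t_slow = fit_loglinear(cstd_slow_post).half_life_or_doubling
        assert t_slow > t_fast * 1.05
        assert t_fast == pytest.approx(7.0, rel=0.05)
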