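import json

import numpy as np
import pytest

from cstdkit import CSTDSeries, classify_periods, evaluate, fit_loglinear, render_report
from cstdkit.recommender import APPARENT_LABEL, CAUTION, INVALID, VALID


def make_series(years, rate=-0.05):
    """Exponential series with natural-log slope ``rate``."""
    years = np.asarray(years, dtype=float)
    conc = 5.0 * np.exp(rate * (years - years[0]))
    return CSTDSeries(years, np.full_like(years, 30.0), conc)


def run(years, rate, t_elim, age_flag=None, t_in=7.0, ban=1970.0):
    s = make_series(years, rate)
    fit = fit_loglinear(s)
    periods = classify_periods(s, ban, t_elim)
    recs = evaluate(fit, periods, t_half_elim_known=t_elim, t_half_in_est=t_in,
                    age_flag=age_flag)
    return fit, recs


WINDOWS = {
    "pre-ban": ([1950.0, 1958.0, 1968.0], +0.099),
    "transition-early": ([1971.0, 1975.0, 1979.0], -0.02),
    "transition-late": ([1984.0, 1990.0, 1996.0], -0.07),
    "post-ban": ([2005.0, 2015.0, 2025.0], -0.09),
}


class TestTruthTable:
    @pytest.mark.parametrize("window_name", list(WINDOWS))
    @pytest.mark.parametrize("t_elim", [3.0, 14.0, None])
    @pytest.mark.parametrize("age_flag", [True, None])
    def test_every_combination_yields_defined_verdicts(self, window_name, t_elim, age_flag):
        years, rate = WINDOWS[window_name]
        fit, recs = run(years, rate, t_elim, age_flag)
        ids = [r.rule_id for r in recs]
        # exactly one verdict per applicable rule
        assert len(ids) == len(set(ids))
        assert all(r.verdict in {VALID, INVALID, CAUTION} for r in recs)
        assert all(r.rule_id in {"R1", "R2", "R3", "R4", "R5"} for r in recs)
        by_id = {r.rule_id: r for r in recs}
        barred = (t_elim == 14.0) or bool(age_flag)  # >= 10 y or > t_in, or age profile
        if barred:
            assert by_id["R5"].verdict == INVALID
            if "R4" in by_id:
                assert by_id["R4"].verdict == INVALID
        if window_name == "pre-ban" and not barred:
            assert by_id["R1"].verdict == VALID
        if window_name == "transition-early":
            assert by_id["R2"].verdict == INVALID

    def test_rapid_post_ban_tool_applicable(self):
        _, recs = run(*WINDOWS["post-ban"], t_elim=3.0)
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R3"].verdict == VALID
        assert by_id["R4"].verdict == VALID
        assert "R5" not in by_id

    def test_unknown_half_life_post_ban_downgraded_to_caution(self):
        years, rate = WINDOWS["post-ban"]
        s = make_series(years, rate)
        fit = fit_loglinear(s)
        recs = evaluate(fit, classify_periods(s, 1970.0, None))  # no t_in either
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R3"].verdict == CAUTION
        assert by_id["R3"].triggers["t_half_in_proxy_from_cstd"]
        assert by_id["R5"].verdict == CAUTION

    def test_r3_overrides_r2_in_late_transition_for_rapid_chemical(self):
        # elimination 6 y < intake halving 12 y; transition 1970-1982
        fit, recs = run([1980.5, 1981.0, 1981.5], -0.06, t_elim=6.0, t_in=12.0)
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R2"].verdict == CAUTION
        assert "verridden" in by_id["R2"].rationale
        assert by_id["R3"].verdict == VALID
        assert by_id["R4"].verdict == VALID

    def test_mixed_window_cautioned_with_split_suggestion(self):
        fit, recs = run([1950.0, 1975.0, 2005.0], -0.01, t_elim=3.0)
        assert any("split" in r.rationale for r in recs)
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R1"].verdict == CAUTION


class TestExamples:
    def test_pre_ban_rising_doubling_time_interpretable(self):
        fit, recs = run(*WINDOWS["pre-ban"], t_elim=None)
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R1"].verdict == VALID
        assert "doubling" in by_id["R1"].rationale

    def test_first_transition_decade_fit_rejected(self):
        """A 1996-2003 window for a chemical phased out in 1995 yields a very
        long apparent halving time that must not be interpreted."""
        fit, recs = run([1996.0, 1999.0, 2003.0], -0.026, t_elim=None, ban=1995.0)
        assert fit.half_life_or_doubling > 20.0
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R2"].verdict == INVALID

    def test_age_flag_rejects_tool_result(self):
        _, recs = run(*WINDOWS["post-ban"], t_elim=7.0, age_flag=True)
        by_id = {r.rule_id: r for r in recs}
        assert by_id["R5"].verdict == INVALID
        assert "age" in by_id["R5"].rationale


class TestOutputSchema:
    def test_cstd_half_life_never_labeled_as_elimination(self):
        """The apparent fitted quantity must never be presented as an
        elimination half-life anywhere in the report."""
        fit, recs = run(*WINDOWS["post-ban"], t_elim=14.0)
        report = render_report(fit, recs)
        assert report["fit"]["quantity"] == APPARENT_LABEL
        assert "apparent" in report["fit"]["quantity"]
        assert not any("elim" in key for key in report["fit"])
        # R5's rationale presents the fitted value only as an upper limit
        r5 = next(r for r in report["recommendations"] if r["rule"] == "R5")
        assert "upper limit" in r5["rationale"]
        json.dumps(report)  # serializable

    def test_report_round_trips_tool_result(self):
        from cstdkit import ExposureScenario, ChemicalParams, StaticBody
        from cstdkit import estimate_elim_halflife, intake_series_from_scenario, static_cstd

        scen = ExposureScenario(1970.0, 7.0, 7.0, 1.0)
        body = StaticBody()
        cstd = static_cstd(body, ChemicalParams(3.0), scen, 30.0,
                           np.arange(2000.0, 2013.0, 4.0))
        tool = estimate_elim_halflife(
            cstd, intake_series_from_scenario(scen, np.arange(1900.0, 2021.0)), body=body
        )
        fit, recs = run(*WINDOWS["post-ban"], t_elim=3.0)
        report = render_report(fit, recs, tool_result=tool)
        assert "halflife_tool" in report
        json.dumps(report)
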