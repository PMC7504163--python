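"""Scenario projection, headline comparison metrics, trajectories."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readgain import (
    Regime,
    ScenarioSpec,
    SegmentCalendar,
    business_as_usual,
    closure_scenario,
    compare_scenarios,
    export_trajectories,
    gain_loss_pct,
    gap_closing_days,
    mitigation_pct,
    project_gain,
    rate_decrease_pct,
    rate_ratio_pct,
)
from readgain import reference
from readgain.scenarios import (
    GapNeverClosesError,
    ScenarioError,
    UndefinedMetricError,
)

ALL = reference.READING_FREQ_TABLE["all"][2:]  # (7.17, 2.46, 8.75) per 100 days


class TestProjectGain:
    def test_business_as_usual_gain(self, cal):
        # 166 days at 7.17/100 + 78 days at 2.46/100
        rep = project_gain(ALL, business_as_usual(cal))
        assert rep.gain == pytest.approx(166 * 0.0717 + 78 * 0.0246, abs=1e-12)
        assert rep.gain == pytest.approx(13.8, abs=0.15)

    def test_closure_gain(self, cal):
        rep = project_gain(ALL, closure_scenario(cal))
        assert rep.gain == pytest.approx(75 * 0.0717 + 169 * 0.0246, abs=1e-12)
        assert rep.gain == pytest.approx(9.5, abs=0.15)

    def test_zero_length_window(self):
        d = date(2020, 3, 16)
        spec = ScenarioSpec(name="empty", regimes=(Regime(d, d, "summer"),))
        assert project_gain(ALL, spec).gain == 0.0

    def test_gap_between_regimes_rejected(self):
        with pytest.raises(ScenarioError, match="contiguous"):
            ScenarioSpec(
                name="bad",
                regimes=(
                    Regime(date(2020, 1, 1), date(2020, 3, 1), "kindergarten"),
                    Regime(date(2020, 3, 2), date(2020, 9, 1), "summer"),
                ),
            )

    def test_accepts_fit_result_rates(self, cal):
        from readgain.ols import FitResult

        fit = FitResult(
            beta_hat=np.array([55.4, 0.0717, 0.0246, 0.0875]),
            cov_beta=np.eye(4), sigma2_hat=1.0, m=100, df_t=96,
        )
        assert project_gain(fit, business_as_usual(cal)).gain == pytest.approx(
            project_gain(ALL, business_as_usual(cal)).gain
        )

    @given(split=st.integers(1, 243))
    @settings(max_examples=50, deadline=None)
    def test_gain_additive_over_interior_split(self, split):
        cal = SegmentCalendar()
        start, end = date(2020, 1, 1), date(2020, 9, 1)
        mid = start + timedelta(days=split)
        whole = project_gain(ALL, closure_scenario(cal)).gain
        # re-slice the closure scenario at an arbitrary interior date
        closure = date(2020, 3, 16)
        def piece(a, b):
            regs = []
            if a < closure and b > a:
                regs.append(Regime(a, min(b, closure), "kindergarten"))
            if b > closure:
                regs.append(Regime(max(a, closure), b, "summer"))
            if not regs:
                regs = [Regime(a, b, "kindergarten" if b <= closure else "summer")]
            return project_gain(ALL, ScenarioSpec(name="p", regimes=tuple(regs))).gain
        assert piece(start, mid) + piece(mid, end) == pytest.approx(whole, abs=1e-9)

    def test_no_closure_before_school_year_end_matches_bau(self):
        cal = SegmentCalendar(
            closure_start=date(2020, 6, 15), school_year_end_2020=date(2020, 6, 15)
        )
        bau = project_gain(ALL, business_as_usual(cal)).gain
        clo = project_gain(ALL, closure_scenario(cal)).gain
        assert clo == pytest.approx(bau, abs=1e-12)


class TestComparisonMetrics:
    def test_rate_decrease_reproduces_published_66pct(self):
        assert round(rate_decrease_pct(7.17, 2.46)) == 66

    def test_gain_loss_reproduces_published_31pct(self, cal):
        bau = project_gain(ALL, business_as_usual(cal)).gain
        clo = project_gain(ALL, closure_scenario(cal)).gain
        assert round(gain_loss_pct(clo, bau)) == 31

    def test_everyday_vs_not_everyday_comparison(self, cal):
        bau = project_gain(ALL, business_as_usual(cal)).gain
        ev = project_gain(reference.READING_FREQ_TABLE["every day"][2:], closure_scenario(cal)).gain
        ne = project_gain(reference.READING_FREQ_TABLE["not every day"][2:], closure_scenario(cal)).gain
        comp = compare_scenarios(ev, ne, bau)
        assert comp.points_less_group == pytest.approx(3.2, abs=0.15)
        assert comp.points_less_reference == pytest.approx(5.5, abs=0.15)
        assert round(comp.mitigation_pct) == 42
        assert comp.mitigation_points == pytest.approx(2.3, abs=0.15)

    def test_self_comparison_mitigates_nothing(self):
        comp = compare_scenarios(9.5, 9.5, 13.8)
        assert comp.mitigation_pct == 0.0
        assert comp.points_less_group == comp.points_less_reference

    def test_percentages_invariant_to_shared_intercept_shift(self):
        # intercepts never enter the percentage metrics; explicit check on
        # gap-closing inputs instead
        d1 = gap_closing_days((50.8, 3.32), (61.4, 1.31))
        d2 = gap_closing_days((50.8 + 7.0, 3.32), (61.4 + 7.0, 1.31))
        assert d1 == pytest.approx(d2)

    @pytest.mark.parametrize(
        "a,b,expected",
        [(3.08, 1.72, 79.0), (2.0, 2.0, 0.0), (4.92, 2.46, 100.0)],
    )
    def test_rate_ratio(self, a, b, expected):
        assert rate_ratio_pct(a, b) == pytest.approx(expected, abs=0.5)

    def test_zero_denominators_named(self):
        with pytest.raises(UndefinedMetricError, match="rate_decrease"):
            rate_decrease_pct(0.0, 1.0)
        with pytest.raises(UndefinedMetricError, match="gain_loss"):
            gain_loss_pct(1.0, 0.0)
        with pytest.raises(UndefinedMetricError, match="mitigation"):
            mitigation_pct(0.0, 1.0)
        with pytest.raises(UndefinedMetricError, match="rate_ratio"):
            rate_ratio_pct(1.0, 0.0)


class TestGapClosing:
    def test_published_socioeconomic_gap(self):
        low = (reference.SES_TABLE["low+low"][1], reference.SES_TABLE["low+low"][3])
        high = (reference.SES_TABLE["high+high"][1], reference.SES_TABLE["high+high"][3])
        days = gap_closing_days(low, high)
        assert days == pytest.approx(10.6 / 2.01 * 100, abs=1e-9)
        assert days == pytest.approx(530, abs=5)

    def test_simulated_trajectories_meet_exactly(self):
        days = gap_closing_days((50.8, 3.32), (61.4, 1.31))
        low_final = 50.8 + 3.32 / 100 * days
        high_final = 61.4 + 1.31 / 100 * days
        assert abs(low_final - high_final) < 1e-9

    def test_equal_intercepts_close_immediately(self):
        assert gap_closing_days((55.0, 3.0), (55.0, 1.0)) == 0.0

    def test_parallel_trajectories_never_close(self):
        with pytest.raises(GapNeverClosesError):
            gap_closing_days((50.0, 2.0), (60.0, 2.0))

    def test_wrong_argument_order_rejected(self):
        with pytest.raises(ValueError, match="lower-intercept"):
            gap_closing_days((61.4, 1.31), (50.8, 3.32))


class TestTrajectories:
    def test_series_start_zero_and_end_at_gain(self, cal):
        reps = [
            project_gain(ALL, business_as_usual(cal)),
            project_gain(ALL, closure_scenario(cal)),
        ]
        df = export_trajectories(reps, step_days=1)
        for rep in reps:
            sub = df[df["scenario"] == rep.scenario].sort_values("date")
            assert sub["score_change"].iloc[0] == 0.0
            assert sub["score_change"].iloc[-1] == pytest.approx(rep.gain, abs=1e-9)

    def test_scenarios_coincide_before_closure(self, cal):
        reps = [
            project_gain(ALL, business_as_usual(cal)),
            project_gain(ALL, closure_scenario(cal)),
        ]
        df = export_trajectories(reps, step_days=1)
        pre = df[df["date"] <= cal.closure_start]
        bau = pre[pre["scenario"] == "business-as-usual"].set_index("date")["score_change"]
        clo = pre[pre["scenario"] == "closure"].set_index("date")["score_change"]
        np.testing.assert_allclose(bau.to_numpy(), clo.to_numpy(), atol=1e-12)

    def test_empty_reports_rejected(self):
        with pytest.raises(ScenarioError):
            export_trajectories([])
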