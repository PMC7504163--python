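"""Counterfactual projection of reading-score gain over dated rate regimes.

A scenario is an ordered, contiguous sequence of regimes, each applying
one of the fitted segment rates (kindergarten / summer / 1st grade) over
a half-open date interval.  Two canonical 2020 scenarios:

* business-as-usual — kindergarten rate until the normal school-year end,
  then the summer rate to the projection end;
* closure — kindergarten rate only until schools closed (week of
  2020-03-16), then the summer rate, which stands in for the rate of gain
  without formal in-person schooling.

Gains are the integral of the daily rate over the window; all comparison
percentages are computed from unrounded intermediates and rounded only
for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import SegmentCalendar
from .ols import FitResult

__all__ = [
    "RATE_SELECTORS",
    "Regime",
    "ScenarioSpec",
    "GainReport",
    "ScenarioError",
    "UndefinedMetricError",
    "business_as_usual",
    "closure_scenario",
    "project_gain",
    "rate_decrease_pct",
    "gain_loss_pct",
    "points_less",
    "mitigation_pct",
    "compare_scenarios",
    "rate_ratio_pct",
    "gap_closing_days",
    "export_trajectories",
]

RATE_SELECTORS = ("kindergarten", "summer", "first_grade")
_SELECTOR_INDEX = {"kindergarten": 1, "summer": 2, "first_grade": 3}


class ScenarioError(ValueError):
    """Regimes leave a gap, overlap, or fall outside the window."""


class UndefinedMetricError(ZeroDivisionError):
    """A comparison metric's denominator is zero; the message names it."""


@dataclass(frozen=True)
class Regime:
    start: date
    end: date
    rate: str  # one of RATE_SELECTORS

    def __post_init__(self) -> None:
        if self.rate not in RATE_SELECTORS:
            raise ScenarioError(f"unknown rate selector {self.rate!r}; choose from {RATE_SELECTORS}")
        if self.end < self.start:
            raise ScenarioError(f"regime ends before it starts: {self.start}..{self.end}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class ScenarioSpec:
    """Named, contiguous sequence of rate regimes covering a window."""

    name: str
    regimes: tuple[Regime, ...]

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ScenarioError("scenario needs at least one regime")
        for prev, nxt in zip(self.regimes, self.regimes[1:]):
            if prev.end != nxt.start:
                raise ScenarioError(
                    f"regimes must be contiguous: {prev.end} != {nxt.start} in scenario {self.name!r}"
                )

    @property
    def window(self) -> tuple[date, date]:
        return self.regimes[0].start, self.regimes[-1].end


def business_as_usual(cal: SegmentCalendar, name: str = "business-as-usual") -> ScenarioSpec:
    """Uninterrupted schooling: kindergarten rate to the school-year end, then summer."""
    return ScenarioSpec(
        name=name,
        regimes=(
            Regime(cal.projection_start, cal.school_year_end_2020, "kindergarten"),
            Regime(cal.school_year_end_2020, cal.projection_end, "summer"),
        ),
    )


def closure_scenario(cal: SegmentCalendar, name: str = "closure") -> ScenarioSpec:
    """School closure: the summer rate replaces schooling from closure_start on."""
    return ScenarioSpec(
        name=name,
        regimes=(
            Regime(cal.projection_start, cal.closure_start, "kindergarten"),
            Regime(cal.closure_start, cal.projection_end, "summer"),
        ),
    )


def _rates_per_day(rates) -> dict[str, float]:
    """Normalize a rate source to per-day rates keyed by selector.

    Accepts a FitResult (per-day coefficients), a mapping of selector to
    per-100-day rate, or a 3-sequence (k, summer, g1) per 100 days — the
    scale the published tables print.
    """
    if isinstance(rates, FitResult):
        return {sel: float(rates.beta_hat[idx]) for sel, idx in _SELECTOR_INDEX.items()}
    if isinstance(rates, Mapping):
        missing = set(RATE_SELECTORS) - set(rates)
        if missing:
            raise ScenarioError(f"rate mapping missing selectors: {sorted(missing)}")
        return {sel: float(rates[sel]) / 100.0 for sel in RATE_SELECTORS}
    seq = list(rates)
    if len(seq) != 3:
        raise ScenarioError("rate sequence must be (kindergarten, summer, first_grade) per 100 days")
    return {sel: float(v) / 100.0 for sel, v in zip(RATE_SELECTORS, seq)}


@dataclass(frozen=True)
class GainReport:
    """Projected gain over a scenario window plus its piecewise trajectory.

    ``trajectory`` holds the cumulative score change at each regime
    boundary; the endpoint equals ``gain``.
    """

    scenario: str
    gain: float
    trajectory: tuple[tuple[date, float], ...]
    rates_per_day: Mapping[str, float] = field(default_factory=dict)

    @property
    def window(self) -> tuple[date, date]:
        return self.trajectory[0][0], self.trajectory[-1][0]


def project_gain(rates, scenario: ScenarioSpec) -> GainReport:
    """Integrate the selected daily rates over the scenario's regimes."""
    per_day = _rates_per_day(rates)
    change = 0.0
    traj = [(scenario.regimes[0].start, 0.0)]
    for reg in scenario.regimes:
        change += reg.days * per_day[reg.rate]
        traj.append((reg.end, change))
    return GainReport(
        scenario=scenario.name,
        gain=change,
        trajectory=tuple(traj),
        rates_per_day=per_day,
    )


def rate_decrease_pct(rate_before: float, rate_after: float) -> float:
    """Percent decrease (1 - after/before) x 100 between two gain rates."""
    if rate_before == 0:
        raise UndefinedMetricError("rate_decrease_pct undefined: reference rate is zero")
    return (1.0 - rate_after / rate_before) * 100.0


def gain_loss_pct(closure_gain: float, bau_gain: float) -> float:
    """Percent of the business-as-usual gain lost under closures."""
    if bau_gain == 0:
        raise UndefinedMetricError("gain_loss_pct undefined: business-as-usual gain is zero")
    return (1.0 - closure_gain / bau_gain) * 100.0


def points_less(bau_reference_gain: float, group_closure_gain: float) -> float:
    """Score points a group gains under closure relative to the reference
    business-as-usual gain (the all-sample projection)."""
    return bau_reference_gain - group_closure_gain


def mitigation_pct(points_less_reference: float, points_less_group: float) -> float:
    """Percent of the reference group's projected loss avoided by the group."""
    if points_less_reference == 0:
        raise UndefinedMetricError("mitigation_pct undefined: reference loss is zero")
    return (points_less_reference - points_less_group) / points_less_reference * 100.0


@dataclass(frozen=True)
class ScenarioComparison:
    points_less_group: float
    points_less_reference: float
    mitigation_pct: float
    mitigation_points: float


def compare_scenarios(
    group_gain: float,
    reference_group_gain: float,
    bau_reference_gain: float,
) -> ScenarioComparison:
    """Compare one group's closure gain against a reference group's.

    Both losses are measured against the same business-as-usual reference
    gain (the all-sample projection); mitigation is the share of the
    reference group's loss that the group avoids.
    """
    pl_group = points_less(bau_reference_gain, group_gain)
    pl_ref = points_less(bau_reference_gain, reference_group_gain)
    return ScenarioComparison(
        points_less_group=pl_group,
        points_less_reference=pl_ref,
        mitigation_pct=mitigation_pct(pl_ref, pl_group),
        mitigation_points=pl_ref - pl_group,
    )


def rate_ratio_pct(rate_a: float, rate_b: float) -> float:
    """How much faster ``rate_a`` is than ``rate_b``, as (a/b - 1) x 100."""
    if rate_b == 0:
        raise UndefinedMetricError("rate_ratio_pct undefined: denominator rate is zero")
    return (rate_a / rate_b - 1.0) * 100.0


class GapNeverClosesError(ValueError):
    """The trailing group does not gain faster, so trajectories never meet."""


def _intercept_and_rate(fit_or_pair, rate_index: int = 2) -> tuple[float, float]:
    if isinstance(fit_or_pair, FitResult):
        return float(fit_or_pair.beta_hat[0]), float(fit_or_pair.beta_hat[rate_index]) * 100.0
    b0, rate_per100 = fit_or_pair
    return float(b0), float(rate_per100)


def gap_closing_days(fit_low, fit_high) -> float:
    """Closure days until the lower-baseline group catches the higher one.

    Arguments are FitResults or ``(intercept, summer_rate_per_100_days)``
    pairs.  With a baseline gap ``g = b0_high - b0_low`` and closure-period
    rates ``r_low > r_high`` (per 100 days), the piecewise-linear
    trajectories intersect after ``g / (r_low - r_high) * 100`` days.
    """
    b0_low, r_low = _intercept_and_rate(fit_low)
    b0_high, r_high = _intercept_and_rate(fit_high)
    gap = b0_high - b0_low
    if gap == 0:
        return 0.0
    if gap < 0:
        raise ValueError("fit_low must be the lower-intercept group")
    diff = r_low - r_high
    if diff <= 0:
        raise GapNeverClosesError(
            f"lower-baseline group's rate ({r_low}) does not exceed the higher group's ({r_high})"
        )
    return gap / diff * 100.0


def export_trajectories(reports: Iterable[GainReport], step_days: int = 1) -> pd.DataFrame:
    """Long-format (scenario, date, score_change) series on a day grid.

    Linear interpolation within regimes; the last grid point is always the
    window end, so each series ends exactly at the scenario's gain.
    """
    reports = list(reports)
    if not reports:
        raise ScenarioError("no gain reports to export")
    if step_days < 1:
        raise ScenarioError("step_days must be >= 1")
    frames = []
    for rep in reports:
        knots_d = [t[0] for t in rep.trajectory]
        knots_v = [t[1] for t in rep.trajectory]
        start, end = knots_d[0], knots_d[-1]
        grid = [start + timedelta(days=k) for k in range(0, (end - start).days, step_days)]
        grid.append(end)
        values = []
        for g in grid:
            # locate containing regime and interpolate
            for i in range(len(knots_d) - 1):
                if knots_d[i] <= g <= knots_d[i + 1]:
                    span = (knots_d[i + 1] - knots_d[i]).days
                    frac = 0.0 if span == 0 else (g - knots_d[i]).days / span
                    values.append(knots_v[i] + frac * (knots_v[i + 1] - knots_v[i]))
                    break
        frames.append(pd.DataFrame({"scenario": rep.scenario, "date": grid, "score_change": values}))
    return pd.concat(frames, ignore_index=True)
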