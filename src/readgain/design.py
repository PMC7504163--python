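"""Segment calendars and piecewise segment-exposure design matrices.

A child's reading trajectory across kindergarten, the intervening summer,
and 1st grade is modeled as a continuous piecewise-linear function of
calendar time.  Each assessment date ``d`` is converted into three
cumulative exposure covariates, measured in whole days with half-open
``[start, end)`` day intervals:

* ``x1`` — days of kindergarten accrued in ``[anchor_date, min(d, k_end))``
* ``x2`` — days of summer accrued in ``[k_end, min(d, g1_start))``
* ``x3`` — days of 1st grade accrued in ``[g1_start, d)``

so that ``x1 + x2 + x3`` always equals the total days elapsed since the
anchor (the date of the first assessment, where the intercept is defined).
The model for a score ``y`` at exposures ``(x1, x2, x3)`` is

    y = b0 + b1*x1 + b2*x2 + b3*x3 + eps

with segment-specific daily gain rates ``b1``, ``b2``, ``b3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, timedelta
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import LongitudinalTable

__all__ = [
    "SegmentCalendar",
    "DesignMatrix",
    "SegmentCalendarError",
    "DesignError",
    "segment_exposures",
    "build_design",
]


class SegmentCalendarError(ValueError):
    """Calendar dates violate the required chronological ordering."""


class DesignError(ValueError):
    """A design matrix cannot be built from the given table/calendar."""


@dataclass(frozen=True)
class SegmentCalendar:
    """Dated boundaries of the schooling segments plus scenario dates.

    Parameters
    ----------
    anchor_date
        Date of the first (kindergarten fall) assessment; the intercept
        of the growth model is the expected score on this day.
    k_end
        First day after the kindergarten year (half-open convention).
    g1_start
        First day of 1st grade; ``[k_end, g1_start)`` is the summer.
    closure_start
        First day of pandemic school closures (week of 2020-03-16).
    projection_start, projection_end
        Window over which scenario gains are projected.
    school_year_end_2020
        Last school day in the business-as-usual 2020 calendar; the
        summer rate applies from here to ``projection_end``.

    The kindergarten/summer boundary dates of the source cohort's school
    year are not published; the defaults below are conventional U.S.
    school-calendar dates and are configuration-visible, not baked into
    any computation.
    """

    anchor_date: date = date(2010, 9, 15)
    k_end: date = date(2011, 6, 15)
    g1_start: date = date(2011, 9, 1)
    closure_start: date = date(2020, 3, 16)
    projection_start: date = date(2020, 1, 1)
    projection_end: date = date(2020, 9, 1)
    school_year_end_2020: date = date(2020, 6, 15)

    def __post_init__(self) -> None:
        if not (self.anchor_date < self.k_end <= self.g1_start):
            raise SegmentCalendarError(
                "require anchor_date < k_end <= g1_start, got "
                f"{self.anchor_date} / {self.k_end} / {self.g1_start}"
            )
        if not (self.projection_start < self.closure_start < self.projection_end):
            raise SegmentCalendarError(
                "require projection_start < closure_start < projection_end, got "
                f"{self.projection_start} / {self.closure_start} / {self.projection_end}"
            )

    @property
    def kindergarten_days(self) -> int:
        return (self.k_end - self.anchor_date).days

    @property
    def summer_days(self) -> int:
        return (self.g1_start - self.k_end).days

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentCalendar":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                kwargs[f.name] = _coerce_date(d[f.name], f.name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name).isoformat() for f in fields(self)}


def _coerce_date(value, name: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise SegmentCalendarError(f"unparseable ISO date for {name!r}: {value!r}") from exc


def segment_exposures(d: date, cal: SegmentCalendar) -> tuple[int, int, int]:
    """Cumulative (kindergarten, summer, 1st-grade) day exposures at date ``d``.

    Raises
    ------
    DesignError
        If ``d`` precedes the calendar's anchor date.
    """
    total = (d - cal.anchor_date).days
    if total < 0:
        raise DesignError(f"date {d} precedes anchor_date {cal.anchor_date}")
    k_len, s_len = cal.kindergarten_days, cal.summer_days
    x1 = min(total, k_len)
    x2 = min(max(total - k_len, 0), s_len)
    x3 = max(total - k_len - s_len, 0)
    return x1, x2, x3


@dataclass(frozen=True)
class DesignMatrix:
    """Stacked regression design ``y = X b + eps`` with exposure columns in days.

    ``X`` has columns ``(1, x1, x2, x3)``; row order follows the source
    table.  ``child_ids`` keeps the per-row provenance for diagnostics.
    """

    X: np.ndarray
    y: np.ndarray
    child_ids: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise DesignError(f"X must be m x 4, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise DesignError("y length must match number of design rows")
        if X.shape[0] == 0:
            raise DesignError("empty design: table contains no records")
        if not np.all(X[:, 0] == 1.0):
            raise DesignError("first design column must be the intercept (all ones)")
        if np.any(X[:, 1:] < 0):
            raise DesignError("negative segment exposure encountered")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def m(self) -> int:
        """Total number of assessment scores (design rows)."""
        return self.X.shape[0]


def exposures_frame(dates: pd.Series, cal: SegmentCalendar) -> pd.DataFrame:
    """Vectorized exposures for a Series of dates; columns x1, x2, x3."""
    days = (pd.to_datetime(dates) - pd.Timestamp(cal.anchor_date)).dt.days.to_numpy()
    if np.any(days < 0):
        raise DesignError("dates precede anchor_date")
    k_len, s_len = cal.kindergarten_days, cal.summer_days
    x1 = np.minimum(days, k_len)
    x2 = np.clip(days - k_len, 0, s_len)
    x3 = np.clip(days - k_len - s_len, 0, None)
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}, index=dates.index)


def build_design(table: "LongitudinalTable", cal: SegmentCalendar) -> DesignMatrix:
    """Assemble the m x 4 design matrix (one row per assessment record).

    Raises
    ------
    DesignError
        If the table is empty or any record is dated before the anchor;
        the error message lists the offending child identifiers.
    """
    df = table.df
    if len(df) == 0:
        raise DesignError("empty design: table contains no records")
    dates = pd.to_datetime(df["date"])
    days = (dates - pd.Timestamp(cal.anchor_date)).dt.days.to_numpy()
    if np.any(days < 0):
        bad = sorted(df.loc[days < 0, "child_id"].unique().tolist())
        raise DesignError(
            f"{len(bad)} children have records before anchor_date "
            f"{cal.anchor_date}: {bad[:10]}"
        )
    expo = exposures_frame(df["date"], cal)
    X = np.column_stack(
        [np.ones(len(df)), expo["x1"], expo["x2"], expo["x3"]]
    ).astype(float)
    return DesignMatrix(
        X=X,
        y=df["score"].to_numpy(dtype=float),
        child_ids=df["child_id"].to_numpy(),
    )


def wave_midpoint(start: date, end: date) -> date:
    """Midpoint of a half-open assessment window, rounded down to a day."""
    return start + timedelta(days=(end - start).days // 2)
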