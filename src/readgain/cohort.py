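"""Synthetic longitudinal cohorts with the piecewise-growth structure.

The restricted-use cohort data behind the published estimates cannot be
redistributed, so every downstream stage is exercised on synthetic
cohorts drawn from the same generative model the analysis assumes: each
child belongs to a category with true coefficients ``(b0, b1, b2, b3)``,
receives four assessment dates (kindergarten fall/spring, 1st-grade
fall/spring), and scores

    y = b0 + b1*x1 + b2*x2 + b3*x3 + N(0, noise_sd^2)

with exposures computed against the same :class:`~readgain.design.SegmentCalendar`
used for fitting.  Errors are independent Gaussian per assessment record
(not per child) — exactly the error structure the estimator assumes, so
nominal confidence-interval coverage is exact by construction.

Randomness: a single integer seed fully determines the output via
``numpy.random.default_rng`` (PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .design import SegmentCalendar, exposures_frame, wave_midpoint

__all__ = [
    "WAVES",
    "CohortConfigError",
    "GroupTruth",
    "CohortConfig",
    "LongitudinalTable",
    "generate_cohort",
    "assign_ses_groups",
]

WAVES = ("K-fall", "K-spring", "G1-fall", "G1-spring")

#: default assessment windows, one half-open (start, end) interval per wave
DEFAULT_WINDOWS: tuple[tuple[date, date], ...] = (
    (date(2010, 9, 15), date(2010, 11, 15)),
    (date(2011, 3, 15), date(2011, 5, 15)),
    (date(2011, 9, 15), date(2011, 11, 15)),
    (date(2012, 3, 15), date(2012, 5, 15)),
)

#: residual score SD calibrated so a full-size cohort reproduces the
#: published summer-rate standard error (~0.51 points per 100 days)
DEFAULT_NOISE_SD = 13.0

TABLE_COLUMNS = [
    "child_id",
    "wave",
    "date",
    "score",
    "reading_freq",
    "income_group",
    "education_group",
]


class CohortConfigError(ValueError):
    """Inconsistent cohort configuration (counts, proportions, windows)."""


class TableError(ValueError):
    """A longitudinal table violates the complete-case contract."""


@dataclass(frozen=True)
class GroupTruth:
    """True generative coefficients and size for one category of children.

    ``beta`` is ``(b0, b1, b2, b3)`` with the intercept in score points and
    the three rates in points per *day*.  Exactly one of ``count`` /
    ``proportion`` should be given.
    """

    beta: tuple[float, float, float, float]
    count: int | None = None
    proportion: float | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Specification of a synthetic cohort.

    By default reproduces the published sample composition: four
    home-reading-frequency categories with exact counts 86 / 752 / 1230 /
    1589 (total 3657) and the published per-category growth coefficients
    as generative truth.
    """

    n_children: int = 3657
    groups: Mapping[str, GroupTruth] = field(default_factory=lambda: default_reading_groups())
    label_kind: str = "reading_freq"  # or "ses"
    noise_sd: float = DEFAULT_NOISE_SD
    assessment_windows: tuple[tuple[date, date], ...] = DEFAULT_WINDOWS
    jitter_dates: bool = False  # False -> deterministic wave midpoints
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise CohortConfigError("n_children must be positive")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be non-negative")
        if self.label_kind not in ("reading_freq", "ses"):
            raise CohortConfigError(f"unknown label_kind {self.label_kind!r}")
        if len(self.assessment_windows) != 4:
            raise CohortConfigError("exactly four assessment windows required")
        flat = [d for w in self.assessment_windows for d in w]
        if any(a >= b for a, b in self.assessment_windows):
            raise CohortConfigError("each assessment window must satisfy start < end")
        if flat != sorted(flat):
            raise CohortConfigError("assessment windows must be chronologically ordered and non-overlapping")
        self._resolve_counts()  # fail fast on inconsistent sizes

    def _resolve_counts(self) -> dict[str, int]:
        counts = {k: g.count for k, g in self.groups.items() if g.count is not None}
        props = {k: g.proportion for k, g in self.groups.items() if g.proportion is not None}
        if counts and props:
            raise CohortConfigError("mix of exact counts and proportions is not supported")
        if counts:
            if len(counts) != len(self.groups):
                raise CohortConfigError("every group needs a count (or use proportions throughout)")
            if sum(counts.values()) != self.n_children:
                raise CohortConfigError(
                    f"group counts sum to {sum(counts.values())}, expected n_children={self.n_children}"
                )
            return counts
        if props:
            if len(props) != len(self.groups):
                raise CohortConfigError("every group needs a proportion")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise CohortConfigError(f"proportions sum to {total}, expected 1")
            # largest-remainder rounding to exact n_children
            raw = {k: p * self.n_children for k, p in props.items()}
            base = {k: int(np.floor(v)) for k, v in raw.items()}
            short = self.n_children - sum(base.values())
            for k in sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)[:short]:
                base[k] += 1
            return base
        raise CohortConfigError("groups must carry counts or proportions")

    @property
    def group_counts(self) -> dict[str, int]:
        return self._resolve_counts()


def default_reading_groups() -> dict[str, GroupTruth]:
    """Published home-reading categories: exact counts + true coefficients."""
    return {
        lab: GroupTruth(beta=reference.beta_per_day(lab), count=reference.READING_FREQ_TABLE[lab][0])
        for lab in reference.BASE_READING_LABELS
    }


def default_ses_groups() -> dict[str, GroupTruth]:
    """Published socioeconomic categories (income x education)."""
    return {
        lab: GroupTruth(
            beta=reference.beta_per_day(lab, reference.SES_TABLE),
            count=reference.SES_TABLE[lab][0],
        )
        for lab in reference.SES_LABELS
    }


class LongitudinalTable:
    """Complete-case long-format table: four assessment records per child.

    Wraps a :class:`pandas.DataFrame` with columns ``child_id, wave, date,
    score, reading_freq, income_group, education_group`` and validates the
    complete-case invariant on construction.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"missing columns: {missing}")
        df = df[TABLE_COLUMNS].copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
            raise TableError("non-finite score values present")
        bad_wave = set(df["wave"]) - set(WAVES)
        if bad_wave:
            raise TableError(f"unknown wave labels: {sorted(bad_wave)}")
        per_child = df.groupby("child_id")["wave"].agg(["count", "nunique"])
        incomplete = per_child[(per_child["count"] != 4) | (per_child["nunique"] != 4)]
        if len(incomplete):
            raise TableError(
                f"{len(incomplete)} children violate the complete-case rule "
                f"(need exactly one record per wave): {incomplete.index.tolist()[:10]}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def n_children(self) -> int:
        return self.df["child_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.df)

    def child_labels(self, column: str) -> pd.Series:
        """One label per child (validated constant within child)."""
        per = self.df.groupby("child_id")[column].agg(["first", "nunique"])
        if (per["nunique"] > 1).any():
            bad = per.index[per["nunique"] > 1].tolist()
            raise TableError(f"label {column!r} varies within children: {bad[:10]}")
        return per["first"]

    def subset(self, child_ids: Sequence) -> "LongitudinalTable":
        keep = self.df["child_id"].isin(set(child_ids))
        return LongitudinalTable(self.df[keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, LongitudinalTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"LongitudinalTable(n_children={self.n_children}, n_records={self.n_records})"


def _draw_dates(config: CohortConfig, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-wave assessment dates for n children (midpoints or uniform jitter)."""
    out = []
    for start, end in config.assessment_windows:
        if config.jitter_dates:
            span = (end - start).days
            offsets = rng.integers(0, span, size=n)
            out.append(np.array([start + pd.Timedelta(days=int(o)) for o in offsets]))
        else:
            out.append(np.full(n, wave_midpoint(start, end)))
    return out


def generate_cohort(config: CohortConfig, cal: SegmentCalendar | None = None) -> LongitudinalTable:
    """Draw a synthetic cohort from the piecewise-linear growth model.

    Children are assigned to groups in a seeded random order, dated
    within each wave window (fixed midpoints unless ``jitter_dates``),
    and scored from their group's true coefficients plus independent
    Gaussian noise.  Identical ``config`` (including seed) gives
    byte-identical output.
    """
    cal = cal or SegmentCalendar()
    for (start, end), wave in zip(config.assessment_windows, WAVES):
        if wave.startswith("K") and end > cal.g1_start:
            raise CohortConfigError(f"{wave} window extends past the kindergarten calendar")
        if start < cal.anchor_date:
            raise CohortConfigError(f"{wave} window starts before anchor_date")
    rng = np.random.default_rng(config.seed)
    counts = config.group_counts
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    n = config.n_children
    ids = np.array([f"C{i:05d}" for i in range(n)])
    dates_by_wave = _draw_dates(config, n, rng)

    beta = np.array([config.groups[lab].beta for lab in labels])  # n x 4
    frames = []
    for w, wave in enumerate(WAVES):
        dates = pd.Series(dates_by_wave[w])
        expo = exposures_frame(dates, cal)
        X = np.column_stack([np.ones(n), expo["x1"], expo["x2"], expo["x3"]])
        mean = np.einsum("ij,ij->i", X, beta)
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "child_id": ids,
                    "wave": wave,
                    "date": dates_by_wave[w],
                    "score": mean + noise,
                    "reading_freq": labels if config.label_kind == "reading_freq" else "every day",
                    "income_group": _ses_part(labels, 0) if config.label_kind == "ses" else "unassigned",
                    "education_group": _ses_part(labels, 1) if config.label_kind == "ses" else "unassigned",
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["child_id", "wave"], key=_wave_sort_key).reset_index(drop=True)
    return LongitudinalTable(df)


def _wave_sort_key(s: pd.Series) -> pd.Series:
    if s.name == "wave":
        order = {w: i for i, w in enumerate(WAVES)}
        return s.map(order)
    return s


def _ses_part(labels: np.ndarray, part: int) -> np.ndarray:
    return np.array([lab.split("+")[part] for lab in labels])


def assign_ses_groups(
    table: LongitudinalTable,
    counts: Mapping[str, int],
    seed: int = 0,
) -> LongitudinalTable:
    """Label children with income+education groups at the given exact counts.

    Labels are ``"low+low", "low+high", "high+low", "high+high"``
    (income group first).  Assignment is a seeded random permutation of
    children; all four records of a child receive the same label.
    """
    n = table.n_children
    if sum(counts.values()) != n:
        raise CohortConfigError(
            f"SES counts sum to {sum(counts.values())}, expected {n} children"
        )
    for lab in counts:
        if "+" not in lab:
            raise CohortConfigError(f"SES label {lab!r} must look like 'income+education'")
    rng = np.random.default_rng(seed)
    children = np.sort(table.df["child_id"].unique())
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    mapping = dict(zip(children, labels))
    df = table.df.copy()
    assigned = df["child_id"].map(mapping)
    df["income_group"] = assigned.str.split("+").str[0]
    df["education_group"] = assigned.str.split("+").str[1]
    return LongitudinalTable(df)
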