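"""Stratified fits: partition the cohort by category and fit per stratum.

Base categories are disjoint and exhaustive over children (e.g. the four
home-reading-frequency responses); derived categories are unions of base
categories (e.g. "not every day" = never + 1-2/week + 3-6/week) and are
always materialized from their constituents, never stored as raw data —
the published count algebra (86 + 752 + 1230 = 2068) identifies them as
derived.  Each stratum is fit independently with the same closed-form
estimator as the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohort import LongitudinalTable
from .design import SegmentCalendar, build_design
from .ols import FitResult, SingularDesignError, fit_ols, rescale_rates

__all__ = [
    "CategoryScheme",
    "StratumFit",
    "StratifiedTable",
    "READING_SCHEME",
    "SES_SCHEME",
    "partition",
    "fit_by_category",
    "coefficient_table",
]


class SchemeError(ValueError):
    """Category scheme inconsistent with the table's labels."""


@dataclass(frozen=True)
class CategoryScheme:
    """How to partition children into strata.

    ``column`` names the per-child label column (``"reading_freq"`` or the
    synthesized ``"ses"`` label ``income+education``); ``base`` lists the
    disjoint exhaustive labels; ``derived`` maps a derived label to the
    base labels it unions.  SES cutoff metadata (income above 185% of the
    federal poverty level; at least one parent holding a bachelor's
    degree) travels with the scheme for provenance but is applied only if
    raw income/education fields are ever supplied upstream.
    """

    column: str
    base: tuple[str, ...]
    derived: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    ses_cutoffs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab, parts in self.derived.items():
            unknown = set(parts) - set(self.base)
            if unknown:
                raise SchemeError(f"derived category {lab!r} references unknown base labels {sorted(unknown)}")


READING_SCHEME = CategoryScheme(
    column="reading_freq",
    base=("never", "1-2/week", "3-6/week", "every day"),
    derived={"not every day": ("never", "1-2/week", "3-6/week")},
)

SES_SCHEME = CategoryScheme(
    column="ses",
    base=("low+low", "low+high", "high+low", "high+high"),
    ses_cutoffs={
        "income": "above 185% federal poverty level",
        "education": "at least one parent with a bachelor's degree",
    },
)


def _label_series(table: LongitudinalTable, scheme: CategoryScheme) -> pd.Series:
    if scheme.column == "ses":
        inc = table.child_labels("income_group")
        edu = table.child_labels("education_group")
        return inc.str.cat(edu, sep="+")
    return table.child_labels(scheme.column)


def partition(table: LongitudinalTable, scheme: CategoryScheme) -> dict[str, LongitudinalTable]:
    """Split a cohort into per-category tables; children move atomically.

    Returns base partitions followed by derived partitions (unions of
    the base tables).  Every child must carry a label in ``scheme.base``.
    """
    labels = _label_series(table, scheme)
    unknown = set(labels.unique()) - set(scheme.base)
    if unknown:
        raise SchemeError(
            f"children carry labels outside the scheme's base categories: {sorted(unknown)}"
        )
    parts: dict[str, LongitudinalTable] = {}
    for lab in scheme.base:
        ids = labels.index[labels == lab]
        if len(ids):
            parts[lab] = table.subset(ids)
    for lab, constituents in scheme.derived.items():
        ids = labels.index[labels.isin(constituents)]
        if len(ids):
            parts[lab] = table.subset(ids)
    return parts


@dataclass(frozen=True)
class StratumFit:
    label: str
    n_children: int
    fit: FitResult | None
    error: str | None = None


@dataclass(frozen=True)
class StratifiedTable:
    """Per-category fit results in scheme order."""

    rows: tuple[StratumFit, ...]

    def __getitem__(self, label: str) -> StratumFit:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]


def fit_by_category(
    partitions: Mapping[str, LongitudinalTable],
    cal: SegmentCalendar,
    sigma2_mode: str = "paper",
) -> StratifiedTable:
    """Fit the growth model independently within each partition.

    A partition too small (or too degenerate) for a full-rank fit is
    recorded with an error message instead of aborting the others.
    """
    rows = []
    for label, sub in partitions.items():
        try:
            fit = fit_ols(build_design(sub, cal), sigma2_mode=sigma2_mode)
            rows.append(StratumFit(label=label, n_children=sub.n_children, fit=fit))
        except SingularDesignError as exc:
            rows.append(StratumFit(label=label, n_children=sub.n_children, fit=None, error=str(exc)))
    return StratifiedTable(rows=tuple(rows))


def coefficient_table(strat: StratifiedTable, factor: float = 100.0) -> pd.DataFrame:
    """Publication-style coefficient table: one row per category.

    Columns: n, then estimate and SE for the intercept and the three
    rates (rates per ``factor`` days).
    """
    records = []
    for row in strat.rows:
        rec: dict = {"category": row.label, "n": row.n_children}
        if row.fit is None:
            rec["error"] = row.error
        else:
            tab = rescale_rates(row.fit, factor=factor)
            for name in tab.index:
                rec[name] = tab.loc[name, "estimate"]
                rec[f"{name}_se"] = tab.loc[name, "se"]
        records.append(rec)
    return pd.DataFrame.from_records(records)
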