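"""Published coefficient estimates for the ECLS-K:2011 kindergarten cohort.

These are the reported piecewise growth-model fits for the 2010-11 U.S.
kindergarten cohort (n = 3657 children with complete assessment and
home-reading data), stratified by home-reading frequency and by family
socioeconomic group.  Rates are score points per 100 days; intercepts are
score points at the kindergarten-fall assessment.

They serve two roles in this package:

* generative truth for synthetic cohorts (round-trip testing), and
* direct inputs to the scenario-projection engine, which operates on
  fitted coefficients rather than raw data.
"""

from __future__ import annotations

# (n_children, intercept, k_rate, summer_rate, g1_rate) — rates per 100 days
READING_FREQ_TABLE: dict[str, tuple[int, float, float, float, float]] = {
    "never": (86, 55.5, 7.71, -0.08, 8.72),
    "1-2/week": (752, 53.5, 6.92, 1.46, 8.25),
    "3-6/week": (1230, 54.8, 7.28, 1.98, 8.85),
    "not every day": (2068, 54.3, 7.17, 1.72, 8.62),
    "every day": (1589, 56.7, 7.22, 3.08, 8.98),
    "all": (3657, 55.4, 7.17, 2.46, 8.75),
}

# standard errors on the same layout
READING_FREQ_SE: dict[str, tuple[float, float, float, float]] = {
    "never": (1.9, 1.40, 4.19, 1.38),
    "1-2/week": (0.5, 0.38, 1.09, 0.37),
    "3-6/week": (0.4, 0.30, 0.86, 0.29),
    "not every day": (0.3, 0.23, 0.67, 0.23),
    "every day": (0.4, 0.28, 0.78, 0.27),
    "all": (0.2, 0.18, 0.51, 0.18),
}

# family income (185% federal poverty line) x parental education (bachelor's)
SES_TABLE: dict[str, tuple[int, float, float, float, float]] = {
    "low+low": (1307, 50.8, 6.41, 3.32, 7.99),
    "low+high": (167, 55.3, 7.38, 3.16, 8.55),
    "high+low": (678, 54.8, 7.03, 2.97, 9.20),
    "high+high": (1222, 61.4, 7.87, 1.31, 9.84),
}

SES_SE: dict[str, tuple[float, float, float, float]] = {
    "low+low": (0.3, 0.25, 0.73, 0.25),
    "low+high": (1.1, 0.81, 2.35, 0.81),
    "high+low": (0.5, 0.35, 1.00, 0.35),
    "high+high": (0.4, 0.32, 0.92, 0.31),
}

BASE_READING_LABELS = ("never", "1-2/week", "3-6/week", "every day")
SES_LABELS = ("low+low", "low+high", "high+low", "high+high")


def beta_per_day(label: str, table: dict | None = None) -> tuple[float, float, float, float]:
    """(b0, b1, b2, b3) with rates converted from per-100-days to per-day."""
    table = READING_FREQ_TABLE if table is None else table
    n, b0, r1, r2, r3 = table[label]
    return (b0, r1 / 100.0, r2 / 100.0, r3 / 100.0)


def group_counts(table: dict | None = None, labels=BASE_READING_LABELS) -> dict[str, int]:
    table = READING_FREQ_TABLE if table is None else table
    return {lab: table[lab][0] for lab in labels}
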