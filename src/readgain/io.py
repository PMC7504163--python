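"""CSV/YAML input-output, run configuration, and end-to-end report assembly.

All tabular data is CSV with ISO-8601 dates and UTF-8 encoding.  Loading
applies the complete-case inclusion rule (children must have all four
assessments) and logs how many children were dropped, along with the
per-stratum sizes and the design condition number — the audit trail a
reproducible reanalysis needs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference
from .cohort import (
    DEFAULT_NOISE_SD,
    DEFAULT_WINDOWS,
    TABLE_COLUMNS,
    WAVES,
    CohortConfig,
    CohortConfigError,
    GroupTruth,
    LongitudinalTable,
    assign_ses_groups,
    generate_cohort,
)
from .design import SegmentCalendar, build_design
from .ols import A_SUMMER_VS_G1, A_SUMMER_VS_K, contrast_test, fit_ols, rescale_rates
from .scenarios import (
    business_as_usual,
    closure_scenario,
    compare_scenarios,
    export_trajectories,
    gain_loss_pct,
    gap_closing_days,
    project_gain,
    rate_decrease_pct,
    rate_ratio_pct,
)
from .stratify import READING_SCHEME, SES_SCHEME, coefficient_table, fit_by_category, partition

logger = logging.getLogger("readgain")

__all__ = [
    "LoadError",
    "RunConfig",
    "read_longitudinal_csv",
    "write_longitudinal_csv",
    "run_full_analysis",
]


class LoadError(ValueError):
    """Input CSV malformed: missing columns, bad dates, duplicate waves."""


def write_longitudinal_csv(table: LongitudinalTable, path) -> None:
    df = table.df.copy()
    df["date"] = df["date"].map(lambda d: d.isoformat())
    df.to_csv(path, index=False)


def read_longitudinal_csv(path) -> LongitudinalTable:
    """Load a long-format cohort CSV, applying the complete-case rule.

    Children missing any of the four waves (or the home-reading label)
    are dropped with a logged count; structural problems — missing
    columns, unparseable dates, duplicate (child, wave) pairs — raise
    :class:`LoadError` naming the offending rows.
    """
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = df.index[parsed.isna()].tolist()
    if bad:
        raise LoadError(f"{path}: unparseable dates at data rows {bad[:10]}")
    df["date"] = parsed.dt.date
    dup = df.duplicated(subset=["child_id", "wave"], keep=False)
    if dup.any():
        raise LoadError(
            f"{path}: duplicate (child_id, wave) pairs at data rows {df.index[dup].tolist()[:10]}"
        )
    waves_per_child = df.groupby("child_id")["wave"].agg(
        lambda s: set(s) == set(WAVES)
    )
    has_label = df.groupby("child_id")["reading_freq"].agg(lambda s: s.notna().all())
    complete = waves_per_child & has_label
    dropped = complete.index[~complete].tolist()
    if dropped:
        logger.info(
            "complete-case filter dropped %d of %d children", len(dropped), len(complete)
        )
        df = df[~df["child_id"].isin(set(dropped))]
    if df.empty:
        raise LoadError(f"{path}: no complete-case children remain")
    return LongitudinalTable(df)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, loadable from YAML.

    When ``input_csv`` is unset a synthetic cohort is generated from
    ``cohort``; SES labels are assigned at the published counts unless
    ``ses_counts`` overrides them.
    """

    calendar: SegmentCalendar = field(default_factory=SegmentCalendar)
    cohort: CohortConfig | None = None
    input_csv: str | None = None
    ses_counts: Mapping[str, int] | None = None
    sigma2_mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_mode not in ("paper", "standard"):
            raise CohortConfigError(f"sigma2_mode must be 'paper' or 'standard', got {self.sigma2_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cal = SegmentCalendar.from_dict(raw.get("calendar", {}))
        seed = int(raw.get("seed", 0))
        cohort_cfg = None
        if "cohort" in raw:
            cohort_cfg = _cohort_from_dict(raw["cohort"], seed)
        elif "input_csv" not in raw:
            cohort_cfg = CohortConfig(seed=seed)
        ses_counts = raw.get("ses_counts")
        if ses_counts is not None:
            ses_counts = {str(k): int(v) for k, v in ses_counts.items()}
        return cls(
            calendar=cal,
            cohort=cohort_cfg,
            input_csv=raw.get("input_csv"),
            ses_counts=ses_counts,
            sigma2_mode=raw.get("sigma2_mode", "paper"),
            seed=seed,
        )


def _cohort_from_dict(raw: dict, seed: int) -> CohortConfig:
    kwargs: dict = {"seed": int(raw.get("seed", seed))}
    if "n_children" in raw:
        kwargs["n_children"] = int(raw["n_children"])
    if "noise_sd" in raw:
        kwargs["noise_sd"] = float(raw["noise_sd"])
    if "jitter_dates" in raw:
        kwargs["jitter_dates"] = bool(raw["jitter_dates"])
    if "label_kind" in raw:
        kwargs["label_kind"] = str(raw["label_kind"])
    if "assessment_windows" in raw:
        kwargs["assessment_windows"] = tuple(
            (pd.Timestamp(a).date(), pd.Timestamp(b).date()) for a, b in raw["assessment_windows"]
        )
    if "groups" in raw:
        groups = {}
        for lab, g in raw["groups"].items():
            if "beta_per100" in g:
                b0, r1, r2, r3 = (float(v) for v in g["beta_per100"])
                beta = (b0, r1 / 100.0, r2 / 100.0, r3 / 100.0)
            else:
                beta = tuple(float(v) for v in g["beta"])
            groups[str(lab)] = GroupTruth(
                beta=beta,
                count=int(g["count"]) if "count" in g else None,
                proportion=float(g["proportion"]) if "proportion" in g else None,
            )
        kwargs["groups"] = groups
    return CohortConfig(**kwargs)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def headline_metrics(
    rates_per100: Mapping[str, tuple[float, float, float]],
    cal: SegmentCalendar,
    intercepts: Mapping[str, float] | None = None,
) -> dict:
    """All derived scenario quantities from per-category (k, summer, g1) rates.

    ``rates_per100`` must contain an ``"all"`` entry; ``"every day"`` and
    ``"not every day"`` entries unlock the home-reading comparison, and
    ``intercepts`` with ``"low+low"`` / ``"high+high"`` (plus matching
    rate entries) unlock the socioeconomic gap-closing projection.
    """
    bau = business_as_usual(cal)
    clo = closure_scenario(cal)
    out: dict = {"scenarios": {}, "metrics": {}}

    all_rates = rates_per100["all"]
    bau_gain = project_gain(all_rates, bau).gain
    closure_gains = {lab: project_gain(r, clo).gain for lab, r in rates_per100.items()}
    out["scenarios"]["business_as_usual_gain"] = bau_gain
    out["scenarios"]["closure_gain"] = {lab: g for lab, g in closure_gains.items()}

    m = out["metrics"]
    m["rate_decrease_pct"] = rate_decrease_pct(all_rates[0], all_rates[1])
    m["gain_loss_pct"] = gain_loss_pct(closure_gains["all"], bau_gain)
    if "every day" in rates_per100 and "not every day" in rates_per100:
        comp = compare_scenarios(
            closure_gains["every day"], closure_gains["not every day"], bau_gain
        )
        m["everyday_points_less"] = comp.points_less_group
        m["not_everyday_points_less"] = comp.points_less_reference
        m["mitigation_pct"] = comp.mitigation_pct
        m["mitigation_points"] = comp.mitigation_points
        m["everyday_summer_rate_advantage_pct"] = rate_ratio_pct(
            rates_per100["every day"][1], rates_per100["not every day"][1]
        )
    if intercepts and {"low+low", "high+high"} <= set(intercepts):
        m["ses_intercept_gap"] = intercepts["high+high"] - intercepts["low+low"]
        try:
            m["gap_closing_days"] = gap_closing_days(
                (intercepts["low+low"], rates_per100["low+low"][1]),
                (intercepts["high+high"], rates_per100["high+high"][1]),
            )
        except ValueError as exc:
            # trailing group not gaining faster (or intercepts reversed):
            # the gap never closes under these fits
            m["gap_closing_days"] = None
            m["gap_closing_note"] = str(exc)
    return out


def _rates_from_coeff_table(df: pd.DataFrame) -> tuple[dict, dict]:
    rates, intercepts = {}, {}
    for _, row in df.iterrows():
        if "error" in df.columns and isinstance(row.get("error"), str) and row.get("error"):
            continue
        rates[row["category"]] = (row["beta1"], row["beta2"], row["beta3"])
        intercepts[row["category"]] = row["beta0"]
    return rates, intercepts


def run_full_analysis(config: RunConfig, outdir) -> dict:
    """Run the whole pipeline and write the report bundle.

    Steps: obtain the cohort (synthetic or CSV), assign SES groups,
    stratify and fit by home-reading frequency and by SES, test the
    summer-vs-school rate contrasts, project the 2020 business-as-usual
    and closure scenarios from the fitted rates, and derive the headline
    comparison metrics.  Deterministic given (config, seed).

    Writes ``cohort.csv``, ``table_reading_freq.csv``, ``table_ses.csv``,
    ``contrasts.csv``, ``gain_report.json`` and ``trajectories.csv`` under
    ``outdir`` and returns the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal = config.calendar

    if config.input_csv:
        table = read_longitudinal_csv(config.input_csv)
    elif config.cohort is not None:
        table = generate_cohort(config.cohort, cal)
    else:
        raise CohortConfigError("config needs either input_csv or a cohort section")

    needs_ses = (table.df["income_group"] == "unassigned").any()
    if needs_ses:
        counts = dict(
            config.ses_counts
            or {lab: reference.SES_TABLE[lab][0] for lab in reference.SES_LABELS}
        )
        total = sum(counts.values())
        if total < table.n_children:
            # the socioeconomic subsample is smaller than the cohort
            # (income/education not reported for every family)
            counts["unknown+unknown"] = table.n_children - total
        if sum(counts.values()) != table.n_children:
            logger.info("skipping SES assignment: counts exceed n_children")
        else:
            table = assign_ses_groups(table, counts, seed=config.seed)
    write_longitudinal_csv(table, outdir / "cohort.csv")
    logger.info("cohort: %d children, %d records", table.n_children, table.n_records)

    design = build_design(table, cal)
    logger.info("design condition number: %.3g", np.linalg.cond(design.X))
    fit_all = fit_ols(design, sigma2_mode=config.sigma2_mode)

    # stratified fits
    strat_read = fit_by_category(partition(table, READING_SCHEME), cal, config.sigma2_mode)
    read_df = coefficient_table(strat_read)
    all_row = coefficient_table_row("all", table.n_children, fit_all)
    read_df = pd.concat([read_df, all_row], ignore_index=True)
    read_df.to_csv(outdir / "table_reading_freq.csv", index=False, float_format="%.6f")

    ses_df = None
    inc = table.child_labels("income_group")
    edu = table.child_labels("education_group")
    ses_labels = inc.str.cat(edu, sep="+")
    known = ses_labels.index[ses_labels.isin(SES_SCHEME.base)]
    if len(known):
        ses_table = table.subset(known)
        strat_ses = fit_by_category(partition(ses_table, SES_SCHEME), cal, config.sigma2_mode)
        ses_df = coefficient_table(strat_ses)
        ses_df.to_csv(outdir / "table_ses.csv", index=False, float_format="%.6f")

    contrasts = pd.DataFrame(
        [
            _contrast_row("summer_vs_kindergarten", fit_all, A_SUMMER_VS_K),
            _contrast_row("summer_vs_first_grade", fit_all, A_SUMMER_VS_G1),
        ]
    )
    contrasts.to_csv(outdir / "contrasts.csv", index=False, float_format="%.6g")

    rates, intercepts = _rates_from_coeff_table(read_df)
    if ses_df is not None:
        r2, i2 = _rates_from_coeff_table(ses_df)
        rates.update(r2)
        intercepts.update(i2)
    report = headline_metrics(rates, cal, intercepts)
    report["fit"] = {
        "all": {
            "n_children": table.n_children,
            "m_scores": fit_all.m,
            "beta_per100": rescale_rates(fit_all)["estimate"].tolist(),
            "se_per100": rescale_rates(fit_all)["se"].tolist(),
            "sigma2_mode": config.sigma2_mode,
        }
    }
    report["contrasts"] = contrasts.to_dict(orient="records")
    report = _round_floats(report)
    (outdir / "gain_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    traj = export_trajectories(
        [
            project_gain(rates["all"], business_as_usual(cal)),
            project_gain(rates["all"], closure_scenario(cal)),
        ]
    )
    traj["date"] = traj["date"].map(lambda d: d.isoformat())
    traj.to_csv(outdir / "trajectories.csv", index=False, float_format="%.6f")
    return report


def coefficient_table_row(label: str, n_children: int, fit) -> pd.DataFrame:
    tab = rescale_rates(fit)
    rec: dict = {"category": label, "n": n_children}
    for name in tab.index:
        rec[name] = tab.loc[name, "estimate"]
        rec[f"{name}_se"] = tab.loc[name, "se"]
    return pd.DataFrame.from_records([rec])


def _contrast_row(name: str, fit, a) -> dict:
    res = contrast_test(fit, a)
    return {
        "contrast": name,
        "estimate_per100": res.z_hat * 100.0,
        "se_per100": np.sqrt(res.var_z) * 100.0,
        "t_stat": res.t_stat,
        "df": res.df,
        "p_two_sided": res.p_two_sided,
    }
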