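"""Stratified cohort analysis of urinary 1-HP against exposure and protection.

Implements the study's statistical workflow: subgroup selection with logged
attrition, multivariable ordinary least squares with t-based confidence
intervals, Pearson correlation for the short-delay stratum, one-way ANOVA,
and a linear-trend contrast across ordered SEMI levels.

Subgroups mirror the study design:

* ``YZ`` — samples collected within 48 h of last exposure, where urinary
  1-HP can still be compared with estimated exposure directly;
* ``single_deployment`` — one rotation only, deployed at least 24 h strictly
  as a firefighter, non-smoker, sample within 14 days, where RPE and skin
  hygiene during the (only) deployment are interpretable;
* ``WX`` — the single-deployment group further restricted to those whose
  first deployment started in the fire's severe first week.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .biomarker import process_samples
from .simulate import SimConfig, compute_exposure_summary
from .types import (
    ExposureSummary,
    FirefighterRecord,
    MonitoringGrid,
    ProcessedSample,
    SmokingStatus,
    ValidationError,
)

__all__ = [
    "SubgroupRule",
    "SUBGROUP_RULES",
    "RegressionTable",
    "AnalysisReport",
    "select_subgroup",
    "ols_fit",
    "fit_semi_model",
    "pearson_r",
    "oneway_anova",
    "linearity_test",
    "run_analysis",
]


@dataclass(frozen=True)
class SubgroupRule:
    """Sequentially applied inclusion criteria; attrition logged per step."""

    name: str
    max_delay_days: int | None = None
    require_single_deployment: bool = False
    require_nonsmoker: bool = False
    require_firefighter_role: bool = False
    require_first_week_start: bool = False
    min_deployment_hours: float = 0.0
    first_week_window: tuple[dt.date, dt.date] = (
        dt.date(2016, 5, 2),
        dt.date(2016, 5, 7),
    )

    def __post_init__(self) -> None:
        if self.max_delay_days is not None and self.max_delay_days <= 0:
            raise ValidationError("max_delay_days must be > 0 when set")
        if self.min_deployment_hours < 0:
            raise ValidationError("min_deployment_hours must be >= 0")


SUBGROUP_RULES: dict[str, SubgroupRule] = {
    "YZ": SubgroupRule(name="YZ", max_delay_days=2),
    "single_deployment": SubgroupRule(
        name="single_deployment",
        max_delay_days=14,
        require_single_deployment=True,
        require_nonsmoker=True,
        require_firefighter_role=True,
        min_deployment_hours=24.0,
    ),
    "WX": SubgroupRule(
        name="WX",
        max_delay_days=14,
        require_single_deployment=True,
        require_nonsmoker=True,
        require_firefighter_role=True,
        require_first_week_start=True,
        min_deployment_hours=24.0,
    ),
}


def select_subgroup(
    cohort: Sequence[FirefighterRecord], rule: SubgroupRule
) -> tuple[list[FirefighterRecord], pd.DataFrame]:
    """Apply the rule's criteria in documented order, logging attrition.

    Returns (subset, attrition table). Criteria are applied sequentially:
    single-deployment, minimum deployed hours, firefighter role, non-smoker,
    collection delay, first-week start; the attrition table has one row per
    criterion with the count entering and the count removed, so
    in = out + excluded at every step.
    """
    steps: list[tuple[str, object]] = [
        ("single_deployment", lambda r: len(r.deployments) == 1),
        (
            "min_deployment_hours",
            lambda r: sum(d.total_hours for d in r.deployments)
            >= rule.min_deployment_hours,
        ),
        ("firefighter_role", lambda r: r.role_firefighter),
        ("nonsmoker", lambda r: r.smoking_status != SmokingStatus.CURRENT),
        (
            "max_delay",
            lambda r: r.sample is not None
            and r.collection_delay_days() <= rule.max_delay_days,
        ),
        (
            "first_week_start",
            lambda r: rule.first_week_window[0]
            <= r.deployments[0].start_date
            <= rule.first_week_window[1],
        ),
    ]
    active = {
        "single_deployment": rule.require_single_deployment,
        "min_deployment_hours": rule.min_deployment_hours > 0,
        "firefighter_role": rule.require_firefighter_role,
        "nonsmoker": rule.require_nonsmoker,
        "max_delay": rule.max_delay_days is not None,
        "first_week_start": rule.require_first_week_start,
    }
    current = list(cohort)
    rows = []
    for name, pred in steps:
        if not active[name]:
            continue
        kept = [r for r in current if pred(r)]
        rows.append(
            {
                "criterion": name,
                "n_in": len(current),
                "n_excluded": len(current) - len(kept),
                "n_out": len(kept),
            }
        )
        current = kept
    attrition = pd.DataFrame(rows, columns=["criterion", "n_in", "n_excluded", "n_out"])
    return current, attrition


@dataclass
class RegressionTable:
    """Per-term OLS estimates with t-based 95% CIs and two-sided p-values."""

    table: pd.DataFrame  # index: term; columns: beta, se, ci_low, ci_high, p
    n: int
    df_resid: int
    r_squared: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X.to_numpy(dtype=float), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [X.columns[j] for j in piv[rank:]]


def ols_fit(y: Sequence[float], X: pd.DataFrame, add_intercept: bool = True) -> RegressionTable:
    """Multivariable least squares of y on the columns of X.

    CIs use t (not normal) quantiles — subgroups here are small. A singular
    design raises, naming the collinear terms rather than silently dropping
    them.
    """
    y = np.asarray(y, dtype=float)
    design = X.copy()
    if add_intercept and "const" not in design.columns:
        design = sm.add_constant(design, has_constant="add")
    n, p = design.shape
    if n <= p:
        raise ValidationError(f"need n > number of terms, got n={n}, terms={p}")
    bad = _collinear_terms(design)
    if bad:
        raise ValidationError(f"singular design; collinear term(s): {sorted(bad)}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return RegressionTable(
        table=table, n=n, df_resid=int(fit.df_resid), r_squared=float(fit.rsquared)
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError(f"need two equal vectors of length >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance input")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F (between/within mean-square ratio) and p.

    Degenerate null data (every group mean identical with zero spread) yield
    F = 0, p = 1 rather than a 0/0 NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    if n_total <= len(arrays):
        raise ValidationError("total observations must exceed number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ssb == 0.0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = st.f_oneway(*arrays)
    return float(f), float(p)


def linearity_test(groups: Mapping[int, Sequence[float]]) -> tuple[float, float]:
    """Linear-trend contrast across ordered group levels (e.g. SEMI 0-3).

    Levels are treated as ordered scores; the contrast coefficients are the
    centred scores, the contrast is evaluated on the group means, and its
    standard error uses the pooled within-group variance with N - k degrees
    of freedom. Returns (t statistic, two-sided p).
    """
    levels = sorted(groups)
    if len(levels) < 2:
        raise ValidationError("linearity test needs at least two levels")
    arrays = [np.asarray(groups[l], dtype=float) for l in levels]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every level needs at least one observation")
    scores = np.asarray(levels, dtype=float)
    c = scores - scores.mean()
    means = np.array([a.mean() for a in arrays])
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    k = len(levels)
    df = n_total - k
    if df <= 0:
        raise ValidationError("no residual degrees of freedom for pooled variance")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    msw = ssw / df
    contrast = float(c @ means)
    if msw == 0.0:
        # zero within-group spread: trend is either exactly absent or infinite
        return (0.0, 1.0) if contrast == 0.0 else (np.inf, 0.0)
    se = float(np.sqrt(msw * (c * c / ns).sum()))
    t = contrast / se
    p = 2.0 * float(st.t.sf(abs(t), df))
    return t, p


# ---------------------------------------------------------------------------
# orchestration


def _design_frame(
    records: Sequence[FirefighterRecord],
    exposures: Mapping[str, ExposureSummary],
    processed: Mapping[str, ProcessedSample],
) -> pd.DataFrame:
    """Analysis frame joining outcome, indices and confounders; complete-case."""
    rows = []
    for r in records:
        ps = processed.get(r.subject_id)
        if ps is None or ps.excluded or r.sample is None:
            continue
        ex = exposures[r.subject_id]
        rows.append(
            {
                "subject_id": r.subject_id,
                "hp_ng_g": ps.hp_ng_per_g_creat,
                "sex_male": float(r.sex == "male"),
                "age": r.age,
                "bmi": r.bmi,
                "smoke_current": float(r.smoking_status == SmokingStatus.CURRENT),
                "smoke_ex": float(r.smoking_status == SmokingStatus.EX),
                "bbq": float(r.bbq_last_48h),
                "role": float(r.role_firefighter),
                "other_fire_14d": float(r.other_fire_14d),
                "service_B": float(r.fire_service == "B"),
                "service_C": float(r.fire_service == "C"),
                "exposure_index": ex.exposure_index,
                "env_total": ex.env_total,
                "rpe_index": ex.rpe_index,
                "semi": float(ex.semi),
                "delay_days": float(r.collection_delay_days()),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame()


CONFOUNDER_TERMS = [
    "sex_male",
    "age",
    "smoke_current",
    "smoke_ex",
    "bmi",
    "bbq",
    "role",
    "other_fire_14d",
    "service_B",
    "service_C",
]

SUBGROUP_TERMS = ["exposure_index", "rpe_index", "semi", "bbq", "other_fire_14d"]

_HYGIENE_FIELDS = {
    "clean_clothes": "clean_clothes",
    "shower": "shower_between_shifts",
    "wash_in_breaks": "wash_in_breaks",
}


@dataclass
class AnalysisReport:
    """Machine-readable mirror of the study's result tables."""

    n_input: int
    n_retained: int
    confounder_model: RegressionTable | None
    subgroup_models: dict[str, RegressionTable | None]
    attrition: dict[str, pd.DataFrame]
    subgroup_n: dict[str, int]
    hygiene_table: pd.DataFrame | None
    semi_anova: tuple[float, float] | None
    linearity: tuple[float, float] | None
    yz_correlation: tuple[float, float, int] | None
    messages: list[str] = field(default_factory=list)

    def render(self) -> str:
        """Plain-text rendering of every table in the report."""
        out = [
            "firefighter smoke-exposure analysis report",
            f"subjects in: {self.n_input}; retained after sample exclusions: {self.n_retained}",
            "",
        ]
        for msg in self.messages:
            out.append(f"note: {msg}")
        if self.confounder_model is not None:
            out += [
                "",
                f"confounder model (all retained subjects, n={self.confounder_model.n})",
                self.confounder_model.table.round(4).to_string(),
            ]
        for name, model in self.subgroup_models.items():
            out += ["", f"subgroup {name}: n={self.subgroup_n.get(name, 0)}"]
            att = self.attrition.get(name)
            if att is not None and not att.empty:
                out.append(att.to_string(index=False))
            if model is not None:
                out.append(model.table.round(4).to_string())
            else:
                out.append("(empty or too small subgroup: no regression fitted)")
        if self.yz_correlation is not None:
            r, p, n = self.yz_correlation
            out += [
                "",
                f"YZ subgroup correlation of 1-HP ng/g creat with total exposure: "
                f"r={r:.4f}, p={p:.4g}, n={n}",
            ]
        if self.hygiene_table is not None:
            out += ["", "mean 1-HP ng/g creat by skin-hygiene factor (WX subgroup)",
                    self.hygiene_table.round(3).to_string(index=False)]
        if self.semi_anova is not None:
            f, p = self.semi_anova
            out.append(f"ANOVA across SEMI levels: F={f:.4f}, p={p:.4g}")
        if self.linearity is not None:
            t, p = self.linearity
            out.append(f"test for linearity across SEMI levels: t={t:.4f}, p={p:.4g}")
        return "\n".join(out) + "\n"


def _safe_ols(frame: pd.DataFrame, terms: list[str]) -> RegressionTable | None:
    usable = [t for t in terms if t in frame.columns and frame[t].nunique() > 1]
    if len(frame) <= len(usable) + 1 or not usable:
        return None
    return ols_fit(frame["hp_ng_g"], frame[usable])


def fit_semi_model(
    cohort: Sequence[FirefighterRecord],
    grid: MonitoringGrid,
    config: SimConfig,
) -> RegressionTable | None:
    """Regression of 1-HP ng/g creat on exposure, RPE, SEMI and confounders
    over all subjects retained after sample exclusions.

    The focused model used by the parameter-recovery and power studies.
    """
    exposures = {
        r.subject_id: compute_exposure_summary(r, grid, config) for r in cohort
    }
    processed = {
        ps.subject_id: ps
        for ps in process_samples(
            [(r.subject_id, r.sample) for r in cohort if r.sample is not None],
            lod=config.lod,
            loq=config.loq,
        )
    }
    frame = _design_frame(cohort, exposures, processed)
    if frame.empty:
        return None
    return _safe_ols(frame, SUBGROUP_TERMS + ["smoke_current", "smoke_ex"])


def run_analysis(
    cohort: Sequence[FirefighterRecord],
    grid: MonitoringGrid,
    config: SimConfig,
) -> AnalysisReport:
    """Run the full stratified workflow on a cohort and PM2.5 grid.

    Produces the confounder regression over all retained subjects, the
    single-deployment and first-week (WX) subgroup regressions, the
    skin-hygiene means table with per-factor ANOVA p and the linear-trend
    test across SEMI levels, and the short-delay (YZ) exposure correlation.
    Empty subgroups yield an explicit empty-subgroup report, not a crash.
    """
    messages: list[str] = []
    exposures = {
        r.subject_id: compute_exposure_summary(r, grid, config) for r in cohort
    }
    with_samples = [(r.subject_id, r.sample) for r in cohort if r.sample is not None]
    skipped = len(cohort) - len(with_samples)
    if skipped:
        messages.append(f"{skipped} subject(s) dropped: no urine sample (complete-case)")
    processed = {
        ps.subject_id: ps
        for ps in process_samples(with_samples, lod=config.lod, loq=config.loq)
    }
    frame = _design_frame(cohort, exposures, processed)
    n_retained = len(frame)

    confounder_model = _safe_ols(frame, CONFOUNDER_TERMS) if n_retained else None

    subgroup_models: dict[str, RegressionTable | None] = {}
    attrition: dict[str, pd.DataFrame] = {}
    subgroup_n: dict[str, int] = {}
    frames: dict[str, pd.DataFrame] = {}
    for name in ("single_deployment", "WX"):
        subset, att = select_subgroup(cohort, SUBGROUP_RULES[name])
        att_ids = [r.subject_id for r in subset]
        sub_frame = frame.loc[frame.index.intersection(att_ids)]
        attrition[name] = att
        subgroup_n[name] = len(sub_frame)
        frames[name] = sub_frame
        if sub_frame.empty:
            messages.append(f"subgroup {name} empty after selection")
            subgroup_models[name] = None
        else:
            subgroup_models[name] = _safe_ols(sub_frame, SUBGROUP_TERMS)

    # short-delay stratum: 1-HP vs task-unweighted total exposure
    yz_subset, yz_att = select_subgroup(cohort, SUBGROUP_RULES["YZ"])
    attrition["YZ"] = yz_att
    yz_frame = frame.loc[frame.index.intersection([r.subject_id for r in yz_subset])]
    subgroup_n["YZ"] = len(yz_frame)
    yz_correlation = None
    if len(yz_frame) >= 3 and yz_frame["env_total"].nunique() > 1:
        r, p = pearson_r(yz_frame["env_total"], yz_frame["hp_ng_g"])
        yz_correlation = (r, p, len(yz_frame))
    elif len(yz_frame) < 3:
        messages.append("YZ subgroup too small for correlation")

    # hygiene-factor means within WX
    wx = frames["WX"]
    hygiene_table = None
    semi_anova = None
    linearity = None
    if not wx.empty:
        by_id = {r.subject_id: r for r in cohort}
        rows = []
        for label, attr in _HYGIENE_FIELDS.items():
            for answer in (False, True):
                ids = [
                    sid for sid in wx.index if getattr(by_id[sid].hygiene, attr) is answer
                ]
                grp = wx.loc[ids]
                if grp.empty:
                    continue
                rows.append(
                    {
                        "factor": label,
                        "answer": "yes" if answer else "no",
                        "n": len(grp),
                        "hp_mean": grp["hp_ng_g"].mean(),
                        "hp_sd": grp["hp_ng_g"].std(ddof=1),
                        "exposure_mean": grp["exposure_index"].mean(),
                        "rpe_mean": grp["rpe_index"].mean(),
                        "delay_mean": grp["delay_days"].mean(),
                    }
                )
            two = [
                wx.loc[[s for s in wx.index if getattr(by_id[s].hygiene, attr) is a],
                       "hp_ng_g"].to_numpy()
                for a in (False, True)
            ]
            if all(len(g) > 0 for g in two) and sum(len(g) for g in two) > 2:
                _, p = oneway_anova(two)
                for row in rows:
                    if row["factor"] == label and "p" not in row:
                        row["p"] = p
        semi_groups = {
            int(level): grp["hp_ng_g"].to_numpy()
            for level, grp in wx.groupby(wx["semi"].astype(int))
        }
        for level in sorted(semi_groups):
            grp = wx[wx["semi"] == level]
            rows.append(
                {
                    "factor": "semi",
                    "answer": str(level),
                    "n": len(grp),
                    "hp_mean": grp["hp_ng_g"].mean(),
                    "hp_sd": grp["hp_ng_g"].std(ddof=1),
                    "exposure_mean": grp["exposure_index"].mean(),
                    "rpe_mean": grp["rpe_index"].mean(),
                    "delay_mean": grp["delay_days"].mean(),
                }
            )
        hygiene_table = pd.DataFrame(rows)
        if len(semi_groups) >= 2 and len(wx) > len(semi_groups):
            semi_anova = oneway_anova(list(semi_groups.values()))
            linearity = linearity_test(semi_groups)

    return AnalysisReport(
        n_input=len(cohort),
        n_retained=n_retained,
        confounder_model=confounder_model,
        subgroup_models=subgroup_models,
        attrition=attrition,
        subgroup_n=subgroup_n,
        hygiene_table=hygiene_table,
        semi_anova=semi_anova,
        linearity=linearity,
        yz_correlation=yz_correlation,
        messages=messages,
    )
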