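"""Survival comparison of desaturation-area metrics.

Each metric column is z-scored and entered as the exposure in a Cox
proportional-hazards model of CVD mortality, adjusted with either a partial
covariate set (demographics, smoking, alcohol, COPD) or a full set that adds
AHI, T90, MinSat and cardio-metabolic comorbidity flags.  Hazard ratios are
therefore per standard deviation of the metric and directly comparable
across metrics with different units.  Significance is read at 0.05 and
trend at 0.10; with the metrics being strongly correlated, no multiplicity
correction is applied.

Fitting is delegated to :class:`lifelines.CoxPHFitter`, which handles tied
event times with the Efron approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import ConvergenceError

__all__ = [
    "SubjectRecord",
    "CoxResult",
    "DegeneratePredictorError",
    "standardize",
    "cohort_frame",
    "fit_cox",
    "comparison_tables",
    "render_comparison",
    "PARTIAL_COVARIATES",
    "FULL_COVARIATES",
]


class DegeneratePredictorError(ValueError):
    """Raised when a metric column is constant and cannot be z-scored."""


@dataclass
class SubjectRecord:
    """Per-subject inputs to the survival stage."""

    subject_id: str
    metrics: dict  # combo label -> metric value
    covariates: dict  # column -> value (see PARTIAL/FULL covariate lists)
    followup_years: float
    cvd_death: int

    def __post_init__(self):
        if not self.followup_years > 0:
            raise ValueError("followup_years must be > 0")
        if self.cvd_death not in (0, 1):
            raise ValueError("cvd_death must be 0 or 1")


@dataclass(frozen=True)
class CoxResult:
    """HR per SD of one metric under one covariate set."""

    label: str
    model: str  # "partial" | "full"
    hr_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    converged: bool = True
    note: str = ""


# Covariate columns expected in the cohort frame.  Categorical covariates are
# entered as dummies: smoking (never reference), TST bins (<=5 h reference).
_DEMOGRAPHICS = [
    "age",
    "male",
    "caucasian",
    "tst_5_8h",
    "tst_ge8h",
    "smoking_former",
    "smoking_current",
    "alcohol",
    "copd",
]
_CARDIOMETABOLIC = [
    "heart_failure",
    "stroke",
    "angina",
    "revascularization",
    "myocardial_infarction",
]
PARTIAL_COVARIATES: tuple[str, ...] = tuple(_DEMOGRAPHICS)
FULL_COVARIATES: tuple[str, ...] = tuple(
    _DEMOGRAPHICS + ["ahi", "t90_pct", "minsat_pct"] + _CARDIOMETABOLIC
)


def standardize(values: Sequence[float], population_sd: bool = True) -> np.ndarray:
    """Z-score a metric column: subtract the mean, divide by the SD.

    Population SD (ddof=0) by convention; set ``population_sd=False`` for the
    sample-SD variant.  A constant column raises
    :class:`DegeneratePredictorError`.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise DegeneratePredictorError("metric column is constant")
    sd = np.nanstd(x, ddof=0 if population_sd else 1)
    return (x - np.nanmean(x)) / sd


def _tst_bins(tst_h: float) -> tuple[int, int]:
    """Dummy-code TST into (<=5 reference, 5-8, >=8) bins."""
    if tst_h >= 8:
        return 0, 1
    if tst_h > 5:
        return 1, 0
    return 0, 0


def cohort_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the modelling DataFrame.

    Smoking and TST categories are dummy-coded here; subjects remain rows and
    complete-case filtering happens at fit time.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for rec in cohort:
        row = {"subject_id": rec.subject_id, "followup_years": rec.followup_years,
               "cvd_death": rec.cvd_death}
        cov = dict(rec.covariates)
        smoking = cov.pop("smoking", None)
        row["smoking_former"] = int(smoking == "former") if smoking is not None else np.nan
        row["smoking_current"] = int(smoking == "current") if smoking is not None else np.nan
        tst = cov.pop("tst_h", np.nan)
        if np.isfinite(tst):
            row["tst_5_8h"], row["tst_ge8h"] = _tst_bins(float(tst))
        else:
            row["tst_5_8h"] = row["tst_ge8h"] = np.nan
        row.update(cov)
        for label, val in rec.metrics.items():
            row[f"metric::{label}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def fit_cox(
    cohort: Sequence[SubjectRecord] | pd.DataFrame,
    combo_label: str,
    model: str = "full",
    min_events: int = 10,
    population_sd: bool = True,
) -> CoxResult:
    """Cox PH fit of CVD death on the z-scored metric plus a covariate set.

    Complete-case analysis: subjects missing the metric, any covariate, or
    the outcome are dropped (counts retrievable from ``n``).  Non-convergence
    or separation yields a flagged result rather than an exception.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    covars = list(PARTIAL_COVARIATES if model == "partial" else FULL_COVARIATES)
    metric_col = f"metric::{combo_label}"
    if metric_col not in df.columns:
        raise KeyError(f"metric {combo_label!r} not in cohort")
    cols = [metric_col, *covars, "followup_years", "cvd_death"]
    data = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n, n_events = len(data), int(data["cvd_death"].sum())
    if n_events < min_events:
        return CoxResult(combo_label, model, np.nan, np.nan, np.nan, np.nan,
                         n, n_events, converged=False, note="insufficient events")
    data = data.copy()
    data["z_metric"] = standardize(data[metric_col].to_numpy(), population_sd)
    data = data.drop(columns=[metric_col])
    # drop constant covariates (e.g. no COPD cases in a small cohort)
    kept = [c for c in covars if data[c].nunique() > 1]
    cph = CoxPHFitter()
    try:
        cph.fit(
            data[["z_metric", *kept, "followup_years", "cvd_death"]],
            duration_col="followup_years",
            event_col="cvd_death",
        )
    except ConvergenceError as exc:
        return CoxResult(combo_label, model, np.nan, np.nan, np.nan, np.nan,
                         n, n_events, converged=False, note=str(exc))
    s = cph.summary.loc["z_metric"]
    return CoxResult(
        label=combo_label,
        model=model,
        hr_per_sd=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n=n,
        n_events=n_events,
    )


def comparison_tables(
    cohort: Sequence[SubjectRecord] | pd.DataFrame,
    combo_labels: Sequence[str],
    models: Sequence[str] = ("partial", "full"),
    alpha: float = 0.05,
    trend: float = 0.10,
) -> pd.DataFrame:
    """Fit every metric under every covariate set and tabulate HR/CI/p.

    Returns a long-format frame with one row per (label, model), flagging
    significance at ``alpha`` and trend at ``trend``.  Metrics that fail to
    fit appear with NaN entries (blank cells in the rendered grid).
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    rows = []
    for model in models:
        for label in combo_labels:
            try:
                r = fit_cox(df, label, model=model)
            except (DegeneratePredictorError, KeyError) as exc:
                r = CoxResult(label, model, np.nan, np.nan, np.nan, np.nan,
                              0, 0, converged=False, note=str(exc))
            rows.append(
                {
                    "label": r.label,
                    "model": r.model,
                    "hr_per_sd": r.hr_per_sd,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "n": r.n,
                    "n_events": r.n_events,
                    "significant": bool(np.isfinite(r.p_value) and r.p_value < alpha),
                    "trend": bool(np.isfinite(r.p_value) and r.p_value < trend),
                    "converged": r.converged,
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)


def render_comparison(table: pd.DataFrame, model: str = "full") -> str:
    """Human-readable HR (CI) grid for one covariate set, annotating p < 0.1."""
    sub = table[table["model"] == model]
    lines = [f"Cox PH comparison ({model} covariate set); HR per SD (95% CI)"]
    for _, row in sub.iterrows():
        if not np.isfinite(row["hr_per_sd"]):
            cell = f"--  [{row['note'] or 'not computed'}]"
        else:
            cell = f"{row['hr_per_sd']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f})"
            if row["p_value"] < 0.1:
                cell += f" p = {row['p_value']:.2g}"
            if row["significant"]:
                cell += " *"
        lines.append(f"  {row['label']:<70s} {cell}")
    return "\n".join(lines)
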