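"""Cohort-level statistics for the ALPS index.

Implements the standard analysis battery for an age-trajectory biomarker
study: inter-observer agreement (Pearson r with a Fisher-z confidence
interval, optional ICC(2,1)), ordinary least-squares regression of the
index on age (whole cohort and an older-than-cutoff subgroup), a
second-degree polynomial fit with its vertex (peak age), and a decade-wise
one-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

Numerical conventions, fixed for reproducibility: the linear fit reports
the *signed* correlation r; the quadratic fit reports the multiple
correlation R = sqrt(R^2) >= 0 (so R >= |r| by model nesting); the
"older than" subgroup filter is strict (age > cutoff); boxplot quartiles
use linear interpolation (quantile type 7) and outliers the 1.5*IQR rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_model import CohortTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS fit of mean index on age (degree 1 or 2).

    ``coefficients`` are (intercept, linear[, quadratic]).  ``r`` is the
    signed Pearson correlation for a linear fit; ``big_r`` the multiple
    correlation sqrt(R^2) for either.  ``band`` is the two-sided 95%
    confidence band of the mean response over an age grid.
    """

    degree: int
    coefficients: tuple[float, ...]
    r: Optional[float]
    big_r: float
    n: int
    vertex_age: Optional[float] = None
    band_ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_lo: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_hi: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted_line: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class GroupSummary:
    """Boxplot-style five-number summary for one decade group."""

    label: str
    n: int
    mean: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_lo: float
    whisker_hi: float
    outliers: list[float]


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    groups: list[GroupSummary]
    pairwise: Optional[pd.DataFrame]  # group1, group2, meandiff, p_adj, reject
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Inter-observer agreement
# ---------------------------------------------------------------------------

def interobserver_correlation(
    table: CohortTable, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson r between the two observers' indices, with a Fisher-z CI.

    Requires exactly two observer columns with no missing values; subjects
    with a missing reading are listed in the error.
    """
    cols = table.observer_columns
    if len(cols) != 2:
        raise ValueError(f"need exactly 2 observers, table has {cols}")
    missing = table.df.loc[table.df[cols].isna().any(axis=1), "subject_id"].tolist()
    if missing:
        raise ValueError(f"subjects missing an observer value: {missing}")
    a = table.df[cols[0]].to_numpy(dtype=float)
    b = table.df[cols[1]].to_numpy(dtype=float)
    r = float(stats.pearsonr(a, b).statistic)
    n = a.size
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, (float(lo), float(hi))


def icc_2_1(table: CohortTable) -> float:
    """ICC(2,1), two-way random effects, absolute agreement, single rater.

    A modern agreement coefficient offered alongside Pearson r; unlike r it
    penalizes systematic observer offsets.
    """
    cols = table.observer_columns
    y = table.df[cols].to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ms_rows = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((y.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(
        (ms_rows - ms_err)
        / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    )


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def _band_grid(ages: np.ndarray, num: int = 101) -> np.ndarray:
    return np.linspace(ages.min(), ages.max(), num)


def linear_fit(
    table: CohortTable, min_age: Optional[float] = None
) -> RegressionResult:
    """OLS of the across-observer mean index on age.

    ``min_age`` applies a strict "older than" filter (age > min_age) before
    fitting, e.g. ``min_age=40`` for the over-40 subgroup.  Requires >= 3
    records after filtering.  ``r`` carries the sign of the slope.
    """
    df = table.df if min_age is None else table.df[table.df["age"] > min_age]
    if len(df) < 3:
        raise ValueError(f"need >= 3 records after age filter, have {len(df)}")
    ages = df["age"].to_numpy(dtype=float)
    y = df["mean_index"].to_numpy(dtype=float)
    x_design = sm.add_constant(ages)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(y, x_design).fit()
        rsq = fit.rsquared
    slope = float(fit.params[1])
    # constant response: R^2 is 0/0; a flat fit explains nothing, so r = 0
    big_r = float(np.sqrt(rsq)) if np.isfinite(rsq) else 0.0
    r = float(np.sign(slope) * big_r) if slope != 0 else 0.0
    grid = _band_grid(ages)
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    return RegressionResult(
        degree=1,
        coefficients=(float(fit.params[0]), slope),
        r=r,
        big_r=big_r,
        n=len(df),
        band_ages=grid,
        band_lo=ci[:, 0],
        band_hi=ci[:, 1],
        fitted_line=pred.predicted_mean,
    )


def quadratic_fit(table: CohortTable) -> RegressionResult:
    """Second-degree OLS of mean index on age; reports R = sqrt(R^2) and the
    vertex age -b1/(2*b2) when the parabola opens downward.

    Requires >= 4 records and >= 3 distinct ages (else the design matrix is
    singular: "degenerate design").
    """
    df = table.df
    ages = df["age"].to_numpy(dtype=float)
    y = df["mean_index"].to_numpy(dtype=float)
    if len(df) < 4:
        raise ValueError(f"need >= 4 records, have {len(df)}")
    if np.unique(ages).size < 3:
        raise ValueError("degenerate design: need >= 3 distinct ages")
    x_design = np.column_stack([np.ones_like(ages), ages, ages**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(y, x_design).fit()
        rsq = fit.rsquared
    b0, b1, b2 = (float(v) for v in fit.params)
    vertex = -b1 / (2.0 * b2) if b2 < 0 else None
    grid = _band_grid(ages)
    pred = fit.get_prediction(np.column_stack([np.ones_like(grid), grid, grid**2]))
    ci = pred.conf_int(alpha=0.05)
    return RegressionResult(
        degree=2,
        coefficients=(b0, b1, b2),
        r=None,
        big_r=float(np.sqrt(rsq)) if np.isfinite(rsq) else 0.0,
        n=len(df),
        vertex_age=vertex,
        band_ages=grid,
        band_lo=ci[:, 0],
        band_hi=ci[:, 1],
        fitted_line=pred.predicted_mean,
    )


# ---------------------------------------------------------------------------
# Decade-wise ANOVA
# ---------------------------------------------------------------------------

def _five_number(label: str, vals: np.ndarray) -> GroupSummary:
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return GroupSummary(
        label=label,
        n=vals.size,
        mean=float(vals.mean()),
        minimum=float(vals.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(vals.max()),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=[float(v) for v in np.sort(outliers)],
    )


def decade_anova(
    table: CohortTable, alpha: float = 0.05, posthoc: bool = True
) -> AnovaResult:
    """One-way ANOVA of mean index across decade groups.

    Groups with fewer than 2 records are dropped (logged); >= 2 usable
    groups are required.  When ``posthoc`` is true, all-pairs comparisons
    are made by Tukey HSD at family-wise level ``alpha``; the pairwise
    table has C(k, 2) rows.  Group five-number summaries use type-7
    quantiles with 1.5*IQR whiskers/outliers.
    """
    grouped = {
        dec: g["mean_index"].to_numpy(dtype=float)
        for dec, g in table.df.groupby("decade", sort=True)
    }
    small = [d for d, v in grouped.items() if v.size < 2]
    if small:
        log.info("decade_anova: dropping groups with < 2 records: %s", small)
    grouped = {d: v for d, v in grouped.items() if v.size >= 2}
    if len(grouped) < 2:
        raise ValueError(f"need >= 2 decade groups with >= 2 records, have {len(grouped)}")

    f_stat, p_val = stats.f_oneway(*grouped.values())
    summaries = [_five_number(d, v) for d, v in sorted(grouped.items())]

    pairwise = None
    if posthoc:
        values = np.concatenate(list(grouped.values()))
        labels = np.concatenate([[d] * v.size for d, v in grouped.items()])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:],
            columns=[str(c) for c in tk.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        groups=summaries,
        pairwise=pairwise,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_cohort(
    table: CohortTable,
    linear: Optional[RegressionResult] = None,
    subgroup: Optional[RegressionResult] = None,
    quadratic: Optional[RegressionResult] = None,
    anova: Optional[AnovaResult] = None,
    out_dir=".",
    stem: str = "cohort",
) -> dict:
    """Scatter + regression-line figure and decade boxplot figure.

    Red line: whole-cohort linear fit; green: older-subgroup linear fit;
    blue: second-degree fit; gray bands: 95% CIs.  Missing fits are simply
    omitted (logged).  Returns a JSON-serializable dict of everything drawn
    (line grids, band edges, boxplot numbers), so outputs can be compared
    exactly across runs; figures are written as PNG.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plot_data: dict = {"scatter": {
        "age": table.df["age"].tolist(),
        "mean_index": [float(v) for v in table.df["mean_index"]],
    }}

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(table.df["age"], table.df["mean_index"], s=12, color="k", zorder=3)
    styles = {"linear": ("red", linear), "subgroup": ("green", subgroup),
              "quadratic": ("blue", quadratic)}
    for name, (color, fit) in styles.items():
        if fit is None:
            log.info("plot_cohort: no %s fit provided; omitted", name)
            continue
        ax.plot(fit.band_ages, fit.fitted_line, color=color, lw=1.5)
        ax.fill_between(fit.band_ages, fit.band_lo, fit.band_hi,
                        color="gray", alpha=0.3, lw=0)
        plot_data[name] = {
            "ages": fit.band_ages.tolist(),
            "line": fit.fitted_line.tolist(),
            "band_lo": fit.band_lo.tolist(),
            "band_hi": fit.band_hi.tolist(),
            "coefficients": list(fit.coefficients),
        }
    ax.set_xlabel("age (years)")
    ax.set_ylabel("ALPS index")
    fig.tight_layout()
    scatter_path = out_dir / f"{stem}_age_index.png"
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)

    box_path = None
    if anova is not None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        stats_list = [
            {
                "label": g.label, "mean": g.mean, "med": g.median,
                "q1": g.q1, "q3": g.q3,
                "whislo": g.whisker_lo, "whishi": g.whisker_hi,
                "fliers": g.outliers,
            }
            for g in anova.groups
        ]
        ax.bxp(stats_list, showfliers=True)
        ax.set_xlabel("age group")
        ax.set_ylabel("ALPS index")
        fig.tight_layout()
        box_path = out_dir / f"{stem}_decade_boxplot.png"
        fig.savefig(box_path, dpi=120)
        plt.close(fig)
        plot_data["boxplot"] = {
            g.label: {
                "n": g.n, "min": g.minimum, "q1": g.q1, "median": g.median,
                "q3": g.q3, "max": g.maximum, "whisker_lo": g.whisker_lo,
                "whisker_hi": g.whisker_hi, "outliers": g.outliers,
            }
            for g in anova.groups
        }

    # basenames only, so serialized plot data is identical across output dirs
    plot_data["files"] = {
        "scatter": scatter_path.name,
        "boxplot": None if box_path is None else box_path.name,
    }
    return plot_data
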