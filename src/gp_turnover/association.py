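"""Bivariate summaries and robust-SE regressions of practice turnover.

Practice-level turnover is related to practice characteristics in two ways:

* boxplot-style five-number summaries per covariate level, using the
  adjacent-value whisker rule (whiskers end at the most extreme data points
  inside p75/p25 +/- 1.5*(p75-p25); points outside are outliers);
* ordinary least squares of the practice-level turnover rate on dummy sets
  for the coded covariates (reference categories: public ownership, city
  location, lowest terciles), with heteroskedasticity-robust (HC1) standard
  errors.

Quantiles use the linear rank-interpolation convention (numpy default),
fixed project-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, ParameterError

__all__ = [
    "boxplot_summary",
    "bivariate_summary",
    "RegressionResult",
    "fit_turnover_regression",
    "format_regression_report",
    "balanced_panel_filter",
    "REGRESSION_SPECS",
]

#: Named regression specifications: the full model, the model without the
#: private-ownership dummy, and the model without the workload dummies.
REGRESSION_SPECS = ("full", "excl_private", "excl_workload")

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def boxplot_summary(values: Iterable, groups: Optional[Iterable] = None) -> pd.DataFrame:
    """Five-number summaries with adjacent-value whiskers, per group.

    Parameters
    ----------
    values
        Numeric observations (e.g. practice or practice-year turnover rates).
    groups
        Optional categorical labels aligned with ``values``; omitted -> one
        summary for the pooled data (labelled ``"all"``). Groups that end up
        empty after dropping missing values are omitted with a warning.

    Returns
    -------
    DataFrame with one row per group: ``group, n, median, p25, p75,
    lower_adjacent, upper_adjacent, n_outliers, outliers``.
    """
    v = pd.Series(list(values), dtype=float)
    g = pd.Series(["all"] * len(v)) if groups is None else pd.Series(list(groups))
    if len(g) != len(v):
        raise ParameterError("values and groups must have equal length")
    rows = []
    for label in g.dropna().unique():
        x = v[(g == label).to_numpy()].dropna().to_numpy()
        if len(x) == 0:
            warnings.warn(f"group {label!r} has no observations; omitted")
            continue
        p25, med, p75 = np.percentile(x, [25, 50, 75])
        iqr = p75 - p25
        lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
        rows.append({
            "group": label, "n": len(x), "median": med, "p25": p25, "p75": p75,
            "lower_adjacent": inside.min(), "upper_adjacent": inside.max(),
            "n_outliers": len(outliers), "outliers": outliers.tolist(),
        })
    return pd.DataFrame(rows, columns=[
        "group", "n", "median", "p25", "p75",
        "lower_adjacent", "upper_adjacent", "n_outliers", "outliers",
    ])


_BIVARIATE_COVARIATES = (
    "size_code", "workload_code", "morbidity_code", "deprivation_code",
    "location", "ownership", "ownership_subtype",
)


def bivariate_summary(turnover: pd.DataFrame, profiles: pd.DataFrame) -> tuple:
    """Boxplot summaries of practice turnover per covariate level.

    Merges practice-level rates with profiles and summarises the rate
    distribution within every level of every available coded covariate
    (including the ownership subtype used in the chain/partnership split).
    Practices without a profile are excluded and reported.

    Returns ``(summaries, excluded)``: a long DataFrame with a ``covariate``
    column, and the list of practice ids lacking a profile.
    """
    merged = turnover.merge(profiles, on="practice_id", how="left", indicator=True)
    excluded = merged.loc[merged["_merge"] != "both", "practice_id"].tolist()
    merged = merged[merged["_merge"] == "both"]
    frames = []
    for cov in _BIVARIATE_COVARIATES:
        if cov not in merged.columns:
            continue
        summary = boxplot_summary(merged["rate"], merged[cov])
        summary.insert(0, "covariate", cov)
        frames.append(summary)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return out, excluded


@dataclass
class RegressionResult:
    """OLS fit of practice turnover on coded covariates with robust SEs."""

    specification: str
    params: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    n_practices: int
    residuals: np.ndarray
    auxiliary: list = field(default_factory=list)  # missing-category dummies, reported but not displayed
    model: object = None  # underlying statsmodels results

    def coefficient_table(self) -> pd.DataFrame:
        stars = self.pvalues.map(_stars)
        return pd.DataFrame({
            "coefficient": self.params,
            "robust_se": self.robust_se,
            "p_value": self.pvalues,
            "stars": stars,
        })


def _stars(p: float) -> str:
    for threshold, mark in _STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def _design_matrix(profiles: pd.DataFrame, specification: str) -> tuple:
    """Dummy design for a regression specification.

    Reference categories (lowest terciles, public, city) are never included.
    Missing-category dummies (code 0) are added when present and flagged as
    auxiliary — they keep practices with a missing covariate in the sample
    without displaying them alongside the substantive coefficients.
    """
    if specification not in REGRESSION_SPECS:
        raise ParameterError(
            f"specification must be one of {REGRESSION_SPECS}, got {specification!r}"
        )
    cols = {}
    auxiliary = []

    def add_terciles(stem: str, allow_missing: bool = True):
        codes = profiles[f"{stem}_code"]
        cols[f"{stem}_2"] = (codes == 2).astype(float)
        cols[f"{stem}_3"] = (codes == 3).astype(float)
        if allow_missing and (codes == 0).any():
            cols[f"{stem}_0"] = (codes == 0).astype(float)
            auxiliary.append(f"{stem}_0")

    add_terciles("size")
    if specification != "excl_workload":
        codes = profiles["workload_code"]
        # workload has no missing category: a missing code drops the practice
        cols["workload_2"] = (codes == 2).astype(float).where(codes.notna())
        cols["workload_3"] = (codes == 3).astype(float).where(codes.notna())
    add_terciles("morbidity")
    add_terciles("deprivation")
    for loc in ("commuting", "town", "rural"):
        cols[f"location_{loc}"] = (profiles["location"].astype(str) == loc).astype(float)
    if specification != "excl_private":
        if "private" in profiles.columns:
            cols["private"] = profiles["private"].astype(float)
        else:
            cols["private"] = (profiles["ownership"].astype(str) == "private").astype(float)
    X = pd.DataFrame(cols, index=profiles.index)
    return X, auxiliary


def fit_turnover_regression(
    turnover: pd.DataFrame,
    profiles: pd.DataFrame,
    specification: str = "full",
) -> RegressionResult:
    """Least-squares fit of practice-level turnover on coded covariates.

    Parameters
    ----------
    turnover
        Practice-level rates (``practice_id, rate``), e.g. from
        :func:`gp_turnover.turnover.practice_average`.
    profiles
        Practice profiles with the tercile codes, location and ownership.
    specification
        ``"full"``, ``"excl_private"`` or ``"excl_workload"``.

    Standard errors are heteroskedasticity-robust with HC1 small-sample
    scaling (the sandwich estimator times n/(n-k)). Rows with a missing
    required covariate are dropped; a rank-deficient design raises
    :class:`EstimationError` naming the collinear columns.
    """
    data = turnover[["practice_id", "rate"]].merge(profiles, on="practice_id", how="inner")
    X, auxiliary = _design_matrix(data, specification)
    complete = X.notna().all(axis=1) & data["rate"].notna()
    X, y = X[complete], data.loc[complete, "rate"]
    n, k = X.shape[0], X.shape[1] + 1
    if n <= k:
        raise EstimationError(f"{n} practices cannot identify {k} coefficients")
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the columns involved in the rank deficiency via QR pivoting
        _, r = np.linalg.qr(Xc.to_numpy())
        bad = [Xc.columns[j] for j in range(Xc.shape[1]) if abs(r[j, j]) < 1e-8]
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y.to_numpy(), Xc).fit(cov_type="HC1")
    return RegressionResult(
        specification=specification,
        params=fit.params,
        robust_se=fit.bse,
        pvalues=fit.pvalues,
        n_practices=int(n),
        residuals=np.asarray(fit.resid),
        auxiliary=auxiliary,
        model=fit,
    )


def format_regression_report(results: Iterable[RegressionResult]) -> str:
    """Plain-text coefficient table across specifications, with significance
    stars at p < 0.05 (*), p < 0.01 (**) and p < 0.001 (***)."""
    results = list(results)
    order: list = []
    for res in results:
        for name in res.params.index:
            if name not in order:
                order.append(name)
    # constant last, auxiliary dummies after the substantive coefficients
    aux = sorted({a for r in results for a in r.auxiliary})
    body = [c for c in order if c != "const" and c not in aux] + aux + ["const"]
    header = f"{'':<22}" + "".join(f"{r.specification:>20}" for r in results)
    lines = [header, "-" * len(header)]
    for name in body:
        coefs, ses = [], []
        for res in results:
            if name in res.params.index:
                coefs.append(f"{res.params[name]:.3f}{_stars(res.pvalues[name])}")
                ses.append(f"({res.robust_se[name]:.3f})")
            else:
                coefs.append("")
                ses.append("")
        lines.append(f"{name:<22}" + "".join(f"{c:>20}" for c in coefs))
        lines.append(f"{'':<22}" + "".join(f"{s:>20}" for s in ses))
    lines.append(f"{'N':<22}" + "".join(f"{r.n_practices:>20}" for r in results))
    lines.append("Robust standard errors in parentheses. "
                 "* p < 0.05, ** p < 0.01, *** p < 0.001.")
    return "\n".join(lines)


def balanced_panel_filter(annual: pd.DataFrame, years: tuple) -> pd.DataFrame:
    """Keep only practices observed in every year of ``years`` (inclusive span)."""
    y0, y1 = int(years[0]), int(years[1])
    span = set(range(y0, y1 + 1))
    window = annual[(annual["year"] >= y0) & (annual["year"] <= y1)]
    present = window.groupby("practice_id", observed=True)["year"].agg(lambda s: set(s))
    complete = present[present.map(lambda s: span <= s)].index
    return window[window["practice_id"].isin(complete)].reset_index(drop=True)
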