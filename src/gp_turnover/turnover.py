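"""Turnover rates at monthly, annual and practice level.

The core statistic: for practice *j* and month *m*, the turnover rate within a
horizon of *h* months is

    Turnover_jm(h) = 100 x  #{workforce members whose spell ends within h months}
                            / #{workforce members of (j, m)}

where a member's spell "ends within h months" iff its last consultation falls
on or before the last day of calendar month m+h. Monthly rates are averaged to
practice-years, practice-years with no regular workforce are imputed with the
practice mean, and practice-year rates are averaged to a time-invariant
practice-level rate used in the association analysis.

A separate rate for permanently employed physicians is computed from
employment records relative to the January workforce: the share of a
practice's January employees whose employment ends during the calendar year.

All rates are carried on the 0-100 percentage scale.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DomainError,
    ImputationError,
    ParameterError,
)

__all__ = [
    "HORIZONS",
    "monthly_turnover",
    "annual_turnover",
    "impute_missing",
    "practice_average",
    "permanent_turnover",
    "mixture_share",
]

#: Follow-up horizons (months) used in the multi-horizon analysis.
HORIZONS = (6, 12, 18, 24, 36, 48, 60)

_CENSOR_POLICIES = ("as_ongoing", "as_ended", "exclude")


def monthly_turnover(
    workforce: pd.DataFrame,
    spells: pd.DataFrame,
    horizon_months: int = 12,
    data_end: Optional[pd.Timestamp] = None,
    censor_policy: str = "as_ongoing",
) -> pd.DataFrame:
    """Per-(practice, month) turnover rate within ``horizon_months``.

    Parameters
    ----------
    workforce
        Roster from :func:`gp_turnover.spells.build_workforce`
        (columns ``practice_id, month, physician_id``).
    spells
        Spell table from :func:`gp_turnover.spells.build_spells`. Every
        workforce member-month must be covered by exactly one spell of its
        (physician, practice) pair.
    horizon_months
        Follow-up horizon h >= 1. Only months whose horizon fits inside the
        data window (end of month m+h <= ``data_end``) are emitted.
    data_end
        Last date of the observation window. Defaults to the latest spell
        ``last_date``.
    censor_policy
        How to treat members whose spell is censored (termination not
        confirmable within the data window): ``as_ongoing`` (default,
        conservative: counted as not ended), ``as_ended`` (counted by the
        observed last date), or ``exclude`` (dropped from numerator and
        denominator).

    Returns
    -------
    DataFrame with columns ``practice_id, month, horizon_months, rate,
    n_workforce, defined`` (rate on the 0-100 scale).
    """
    if not (isinstance(horizon_months, (int, np.integer)) and horizon_months >= 1):
        raise ParameterError(f"horizon_months must be an integer >= 1, got {horizon_months!r}")
    if censor_policy not in _CENSOR_POLICIES:
        raise ParameterError(
            f"censor_policy must be one of {_CENSOR_POLICIES}, got {censor_policy!r}"
        )
    h = int(horizon_months)
    if data_end is None:
        data_end = spells["last_date"].max()
    data_end = pd.Timestamp(data_end).normalize()

    wf = workforce.loc[:, ["practice_id", "month", "physician_id"]].copy()
    if not isinstance(wf["month"].dtype, pd.PeriodDtype):
        wf["month"] = pd.PeriodIndex(wf["month"], freq="M")
    horizon_end = (wf["month"] + h).dt.end_time.dt.normalize()
    wf = wf[horizon_end <= data_end].copy()
    if wf.empty:
        return pd.DataFrame(
            columns=["practice_id", "month", "horizon_months", "rate", "n_workforce", "defined"]
        )

    merged = wf.merge(
        spells[["physician_id", "practice_id", "first_date", "last_date", "censored"]],
        on=["physician_id", "practice_id"],
        how="left",
    )
    month_start = merged["month"].dt.start_time
    month_end = merged["month"].dt.end_time.dt.normalize()
    covers = (merged["first_date"] <= month_end) & (merged["last_date"] >= month_start)
    covering = merged[covers.fillna(False)]
    # every member-month must map to exactly one covering spell
    key = ["practice_id", "month", "physician_id"]
    if len(covering) != len(wf) or covering.duplicated(key).any():
        n_unmatched = len(wf) - covering[key].drop_duplicates().shape[0]
        raise ConsistencyError(
            f"workforce/spell mismatch: {n_unmatched} member-months without a "
            "unique covering spell (were spells built from the same events?)"
        )
    covering = covering.copy()
    hz_end = (covering["month"] + h).dt.end_time.dt.normalize()
    ended = covering["last_date"] <= hz_end
    if censor_policy == "as_ongoing":
        ended &= ~covering["censored"]
    elif censor_policy == "exclude":
        covering = covering[~covering["censored"]]
        ended = ended[covering.index]
    out = (
        pd.DataFrame({
            "practice_id": covering["practice_id"],
            "month": covering["month"],
            "ended": ended.astype(float),
        })
        .groupby(["practice_id", "month"], observed=True)
        .agg(rate=("ended", "mean"), n_workforce=("ended", "size"))
        .reset_index()
    )
    out["rate"] *= 100.0
    out["horizon_months"] = h
    out["defined"] = True
    cols = ["practice_id", "month", "horizon_months", "rate", "n_workforce", "defined"]
    return out.loc[:, cols].sort_values(["practice_id", "month"], ignore_index=True)


def annual_turnover(
    monthly: pd.DataFrame,
    panel: Optional[Iterable] = None,
) -> pd.DataFrame:
    """Average monthly rates to the practice-year level.

    Only months with a defined rate (a non-empty regular workforce) enter the
    mean. When ``panel`` — an iterable of (practice_id, year) pairs or a
    DataFrame with those columns — is given, pairs without any defined month
    are emitted with a missing rate and ``n_months_defined = 0``, ready for
    :func:`impute_missing`.
    """
    if len(monthly) and monthly["horizon_months"].nunique() > 1:
        raise ParameterError(
            f"annual aggregation requires a single horizon, got {sorted(monthly['horizon_months'].unique())}"
        )
    m = monthly.copy()
    if len(m):
        if not isinstance(m["month"].dtype, pd.PeriodDtype):
            m["month"] = pd.PeriodIndex(m["month"], freq="M")
        m["year"] = m["month"].dt.year
        annual = (
            m.groupby(["practice_id", "year"], observed=True)
            .agg(rate=("rate", "mean"), n_months_defined=("rate", "size"))
            .reset_index()
        )
    else:
        annual = pd.DataFrame(columns=["practice_id", "year", "rate", "n_months_defined"])
    annual["imputed"] = False
    if panel is not None:
        if isinstance(panel, pd.DataFrame):
            pairs = panel.loc[:, ["practice_id", "year"]].drop_duplicates()
        else:
            pairs = pd.DataFrame(list(panel), columns=["practice_id", "year"]).drop_duplicates()
        annual = pairs.merge(annual, on=["practice_id", "year"], how="left")
        annual["n_months_defined"] = annual["n_months_defined"].fillna(0).astype(int)
        annual["imputed"] = annual["imputed"].eq(True)
    annual["n_months_defined"] = annual["n_months_defined"].astype(int)
    return annual.sort_values(["practice_id", "year"], ignore_index=True)


def impute_missing(annual: pd.DataFrame) -> pd.DataFrame:
    """Fill practice-years with no regular workforce with the practice mean.

    Rows with a missing rate receive the mean of the practice's observed
    annual rates and are flagged ``imputed``. A practice with no observed year
    at all cannot be imputed and raises :class:`ImputationError`.
    """
    out = annual.copy()
    missing = out["rate"].isna()
    if not missing.any():
        return out
    observed_mean = out.loc[~missing].groupby("practice_id", observed=True)["rate"].mean()
    no_basis = sorted(set(out.loc[missing, "practice_id"]) - set(observed_mean.index))
    if no_basis:
        raise ImputationError(
            f"cannot impute practices with no observed annual rate: {no_basis}"
        )
    out.loc[missing, "rate"] = out.loc[missing, "practice_id"].map(observed_mean).to_numpy()
    out.loc[missing, "imputed"] = True
    return out


def practice_average(annual: pd.DataFrame) -> pd.DataFrame:
    """Time-invariant practice-level turnover: mean of annual rates.

    Expects a post-imputation panel (no missing rates). Records the number of
    panel years per practice.
    """
    if len(annual) == 0:
        return pd.DataFrame(columns=["practice_id", "rate", "n_years"])
    if annual["rate"].isna().any():
        raise ParameterError(
            "practice_average expects a complete (post-imputation) annual panel"
        )
    out = (
        annual.groupby("practice_id", observed=True)
        .agg(rate=("rate", "mean"), n_years=("rate", "size"))
        .reset_index()
    )
    out["n_years"] = out["n_years"].astype(int)
    return out.sort_values("practice_id", ignore_index=True)


def permanent_turnover(
    employment: pd.DataFrame,
    year: int,
    contract: str = "permanent",
) -> pd.DataFrame:
    """Annual turnover of employees on a given contract, relative to January.

    The denominator is the number of physicians with a ``contract`` employment
    record at the practice covering 31 January of ``year`` (open-ended records
    count as ongoing); the numerator is the subset whose employment ends
    during ``year``. Practices with an empty January workforce are omitted.

    Returns a DataFrame with columns ``practice_id, year, rate, n_january,
    n_quit``.
    """
    emp = employment[employment["contract"].astype(str) == str(contract)].copy()
    if emp.empty:
        raise ParameterError(f"no employment records with contract {contract!r}")
    for col in ("start_date", "end_date"):
        if not pd.api.types.is_datetime64_any_dtype(emp[col]):
            emp[col] = pd.to_datetime(emp[col], errors="coerce")
    lo = int(emp["start_date"].min().year)
    if emp["end_date"].isna().any():
        hi = None  # open-ended records: the window has no upper bound
    else:
        hi = max(int(emp["start_date"].max().year), int(emp["end_date"].max().year))
    if int(year) < lo or (hi is not None and int(year) > hi):
        raise ParameterError(
            f"year {year} outside the employment-data window [{lo}, {hi}]"
        )
    jan31 = pd.Timestamp(int(year), 1, 31)
    active = emp[
        (emp["start_date"] <= jan31)
        & (emp["end_date"].isna() | (emp["end_date"] >= jan31))
    ].copy()
    active["quit"] = (active["end_date"].dt.year == int(year)).fillna(False)
    # a physician holding several overlapping records at one practice counts once
    per_phys = (
        active.groupby(["practice_id", "physician_id"], observed=True)["quit"]
        .all()
        .reset_index()
    )
    out = (
        per_phys.groupby("practice_id", observed=True)
        .agg(n_january=("quit", "size"), n_quit=("quit", "sum"))
        .reset_index()
    )
    out["rate"] = 100.0 * out["n_quit"] / out["n_january"]
    out["year"] = int(year)
    cols = ["practice_id", "year", "rate", "n_january", "n_quit"]
    return out.loc[:, cols].sort_values("practice_id", ignore_index=True)


def mixture_share(
    overall_rate: float,
    permanent_rate: float,
    temporary_exit_prob: float = 100.0,
) -> float:
    """Temporary-worker share implied by overall and permanent turnover rates.

    Solves ``overall = (1 - s) * permanent + s * temporary_exit_prob`` for the
    share *s* of the regular workforce on temporary contracts, assuming
    temporary spells end within the year with probability
    ``temporary_exit_prob`` (in percent; 100 by default). All rates are on the
    0-100 scale.
    """
    if not permanent_rate < temporary_exit_prob:
        raise ParameterError(
            f"permanent_rate ({permanent_rate}) must be below temporary_exit_prob "
            f"({temporary_exit_prob})"
        )
    if not (permanent_rate <= overall_rate <= temporary_exit_prob):
        raise DomainError(
            f"overall rate {overall_rate} outside the feasible range "
            f"[{permanent_rate}, {temporary_exit_prob}]"
        )
    return (overall_rate - permanent_rate) / (temporary_exit_prob - permanent_rate)
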