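"""Practice-level covariates with tercile and missing-category coding.

Practice characteristics enter the association analysis as categorical codes:
continuous measures (list size, morbidity, deprivation, workload) are coded
1/2/3 by terciles of the distribution of practice-level averages, with 0
reserved for missing values (workload has no missing level in the reference
coding). Ownership is public/private with an ownership subtype retained for
the chain/partnership split, and location is a four-way municipality class.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .spells import workforce_sizes

__all__ = ["compute_workload", "tercile_code", "build_profiles"]


def compute_workload(registration: pd.DataFrame, workforce: pd.DataFrame) -> pd.DataFrame:
    """Registered patients per workforce physician, averaged to practice level.

    For every month with a defined (non-empty) regular workforce, the ratio
    registered patients / workforce size is formed; the practice-level
    workload is the unweighted mean of these monthly ratios. Months without a
    defined workforce (or without a registration count) contribute nothing;
    a practice with no such month has a missing workload.

    Parameters
    ----------
    registration
        ``practice_id, month, patients`` (one row per practice-month).
    workforce
        Roster from :func:`gp_turnover.spells.build_workforce`, or an already
        collapsed ``practice_id, month, size`` table.

    Returns
    -------
    DataFrame ``practice_id, workload, n_months`` (one row per practice with
    at least one defined month).
    """
    reg = registration.loc[:, ["practice_id", "month", "patients"]].copy()
    if not isinstance(reg["month"].dtype, pd.PeriodDtype):
        reg["month"] = pd.PeriodIndex(reg["month"], freq="M")
    if "size" in workforce.columns:
        sizes = workforce.loc[:, ["practice_id", "month", "size"]].copy()
    else:
        sizes = workforce_sizes(workforce)
    if not isinstance(sizes["month"].dtype, pd.PeriodDtype):
        sizes["month"] = pd.PeriodIndex(sizes["month"], freq="M")
    merged = reg.merge(sizes, on=["practice_id", "month"], how="inner")
    merged = merged[merged["size"] > 0]
    merged["ratio"] = merged["patients"] / merged["size"]
    out = (
        merged.groupby("practice_id", observed=True)
        .agg(workload=("ratio", "mean"), n_months=("ratio", "size"))
        .reset_index()
    )
    out["n_months"] = out["n_months"].astype(int)
    return out.sort_values("practice_id", ignore_index=True)


def tercile_code(values: pd.Series) -> pd.Series:
    """Code a practice-level measure into terciles: 0 missing, 1 low ... 3 high.

    Rank-based rule: with n non-missing values, a value of minimum-rank r gets
    code ``floor(3 * (r - 1) / n) + 1``. Ties share their group's minimum rank
    and therefore fall into the lower tercile; when all values are distinct
    the three groups differ in size by at most one. Missing values get 0.
    """
    v = pd.Series(values).astype(float)
    n = int(v.notna().sum())
    if n == 0:
        raise InputError("tercile coding impossible: all values missing")
    if n < 3:
        raise InputError(f"tercile coding needs >= 3 non-missing values, got {n}")
    ranks = v.rank(method="min")
    codes = np.floor(3.0 * (ranks - 1.0) / n) + 1.0
    codes = codes.where(v.notna(), 0.0).astype(int)
    codes.name = getattr(values, "name", None)
    return codes


def build_profiles(
    attributes: pd.DataFrame,
    registration: pd.DataFrame,
    workforce: pd.DataFrame,
    practices: Optional[pd.Index] = None,
) -> tuple:
    """Assemble one covariate profile per practice.

    Combines the attribute table (ownership, subtype, location, morbidity,
    deprivation), mean registered patients (size), and the workload computed
    from registration counts and workforce sizes, then applies tercile/missing
    coding to the continuous measures.

    Parameters
    ----------
    attributes, registration, workforce
        Tables keyed by ``practice_id`` (see :mod:`gp_turnover.io` schemas).
    practices
        Optional index of practice ids defining the analysis panel. Defaults
        to the practices present in ``attributes``.

    Returns
    -------
    (profiles, report)
        ``profiles``: one row per practice with raw values, codes
        (``size_code, morbidity_code, deprivation_code`` in {0,1,2,3};
        ``workload_code`` in {1,2,3} or missing) and a ``private`` indicator.
        ``report``: dict listing practices with missing attributes or
        missing underlying values.
    """
    attrs = attributes.copy()
    attrs["practice_id"] = attrs["practice_id"].astype(str)
    if practices is None:
        panel_ids = pd.Index(attrs["practice_id"].unique(), name="practice_id")
    else:
        panel_ids = pd.Index(pd.Series(list(practices)).astype(str).unique(), name="practice_id")
    profiles = pd.DataFrame({"practice_id": panel_ids.sort_values()})
    keep = ["practice_id", "ownership", "ownership_subtype", "location",
            "morbidity", "deprivation"]
    keep = [c for c in keep if c in attrs.columns]
    profiles = profiles.merge(attrs.loc[:, keep], on="practice_id", how="left")

    size = (
        registration.assign(practice_id=registration["practice_id"].astype(str))
        .groupby("practice_id", observed=True)["patients"]
        .mean()
        .rename("size_patients")
        .reset_index()
    )
    profiles = profiles.merge(size, on="practice_id", how="left")
    wl = compute_workload(registration, workforce)
    wl["practice_id"] = wl["practice_id"].astype(str)
    profiles = profiles.merge(wl[["practice_id", "workload"]], on="practice_id", how="left")

    for raw, code in (
        ("size_patients", "size_code"),
        ("morbidity", "morbidity_code"),
        ("deprivation", "deprivation_code"),
    ):
        if raw in profiles.columns:
            profiles[code] = tercile_code(profiles[raw])
        else:
            profiles[raw] = np.nan
            profiles[code] = 0
    # workload has no missing category in the reference coding; practices
    # without a defined month keep a missing code and are reported.
    wl_codes = tercile_code(profiles["workload"]).astype(float)
    profiles["workload_code"] = wl_codes.where(wl_codes > 0, np.nan)
    profiles["private"] = (profiles["ownership"].astype(str) == "private").astype(int)

    missing_attrs = profiles.loc[profiles["ownership"].isna(), "practice_id"].tolist()
    missing_values = {
        col: profiles.loc[profiles[col].isna(), "practice_id"].tolist()
        for col in ("size_patients", "morbidity", "deprivation", "workload")
        if profiles[col].isna().any()
    }
    report = {
        "n_practices": int(len(profiles)),
        "missing_attributes": missing_attrs,
        "missing_values": missing_values,
    }
    return profiles, report
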