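"""File schemas, panel-inclusion filters, and the end-to-end pipeline.

All interchange is plain CSV (comma-separated, header row, UTF-8, ISO-8601
dates, months as ``YYYY-MM``):

* ``events``:       physician_id, practice_id, date [, n_visits]
* ``employment``:   physician_id, practice_id, contract, start_date, end_date
* ``registration``: practice_id, month, patients
* ``attributes``:   practice_id, ownership, ownership_subtype, location,
                    morbidity, deprivation, open_year, close_year

:func:`run_pipeline` ties the stages together — simulate (or load), filter
the panel, build rosters and spells, compute turnover at all levels, code
covariates, summarise and regress — writing every intermediate plus a
manifest so the record counts at each stage are checkable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    REGRESSION_SPECS,
    bivariate_summary,
    boxplot_summary,
    fit_turnover_regression,
    format_regression_report,
)
from .config import PanelDefinition, SimulationConfig
from .covariates import build_profiles
from .errors import ConfigurationError, InputError
from .simulate import SyntheticRegistry, generate_registry
from .spells import build_spells, build_workforce, return_fraction, workforce_sizes
from .turnover import (
    annual_turnover,
    impute_missing,
    monthly_turnover,
    practice_average,
)

logger = logging.getLogger("gp_turnover")

__all__ = [
    "read_events", "write_events",
    "read_employment", "write_employment",
    "read_registration", "write_registration",
    "read_attributes", "write_attributes",
    "write_table", "read_table",
    "panel_pairs", "apply_panel_filters", "run_pipeline",
]

ATTRIBUTE_COLUMNS = [
    "practice_id", "ownership", "ownership_subtype", "location",
    "morbidity", "deprivation", "open_year", "close_year",
]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what} table lacks required columns {missing}")


def _parse_dates(df: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    for col in columns:
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy())[:10])
            raise InputError(f"{what}: unparseable {col} at row indices {rows}")
        df[col] = parsed
    return df


# -- readers / writers ------------------------------------------------------

def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"physician_id": str, "practice_id": str})
    _require(df, ["physician_id", "practice_id", "date"], "events")
    return _parse_dates(df, ["date"], "events")


def write_events(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_employment(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"physician_id": str, "practice_id": str, "contract": str})
    _require(df, ["physician_id", "practice_id", "contract", "start_date", "end_date"], "employment")
    df = _parse_dates(df, ["start_date", "end_date"], "employment")
    closed = df["start_date"].notna() & df["end_date"].notna()
    if (df.loc[closed, "start_date"] > df.loc[closed, "end_date"]).any():
        raise InputError("employment: start_date after end_date")
    return df


def write_employment(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("start_date", "end_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_registration(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"practice_id": str})
    _require(df, ["practice_id", "month", "patients"], "registration")
    df["month"] = pd.PeriodIndex(df["month"].astype(str), freq="M")
    return df


def write_registration(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)


def read_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"practice_id": str})
    _require(df, ["practice_id", "ownership", "location"], "attributes")
    if "close_year" in df.columns:
        df["close_year"] = df["close_year"].astype("Int64")
    return df


def write_attributes(df: pd.DataFrame, path) -> None:
    cols = [c for c in ATTRIBUTE_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic writer for derived tables; Period columns become YYYY-MM."""
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.PeriodDtype):
            out[col] = out[col].astype(str)
        elif pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_table(path, month_columns=()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"practice_id": str, "physician_id": str})
    for col in month_columns:
        df[col] = pd.PeriodIndex(df[col].astype(str), freq="M")
    return df


# -- panel filters ----------------------------------------------------------

def _operating_window(attributes: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    attrs = attributes.copy()
    attrs["practice_id"] = attrs["practice_id"].astype(str)
    open_year = attrs["open_year"] if "open_year" in attrs else pd.Series(panel.start_year, index=attrs.index)
    close_year = attrs["close_year"] if "close_year" in attrs else pd.Series(pd.NA, index=attrs.index)
    first = np.maximum(open_year.fillna(panel.start_year).astype(int), panel.start_year)
    last_operating = close_year.fillna(panel.end_year).astype(int)
    closes_in_window = close_year.notna() & (close_year <= panel.end_year)
    last = np.minimum(last_operating, panel.end_year)
    out = pd.DataFrame({
        "practice_id": attrs["practice_id"],
        "first_year": first,
        "last_year": last,
        "closes_in_window": closes_in_window,
    })
    out["last_panel_year"] = out["last_year"] - np.where(
        out["closes_in_window"] & panel.exclude_closure_year, 1, 0
    )
    out["years_operating"] = out["last_year"] - out["first_year"] + 1
    return out


def apply_panel_filters(
    events: pd.DataFrame,
    attributes: pd.DataFrame,
    panel: PanelDefinition,
) -> tuple:
    """Apply the study-population rules and report the inclusion accounting.

    Practices operating fewer than ``min_years_operating`` calendar years
    inside the panel window are removed with all their events; for practices
    that close inside the window the closure-year events are dropped (the
    closure year never enters the panel). Events outside the attribute table's
    practices are an input error.

    Returns ``(filtered_events, report)`` where the report lists the included
    practices, exclusions with reasons, and the resulting practice-year count.
    """
    panel.validate()
    ev = events.copy()
    ev["practice_id"] = ev["practice_id"].astype(str)
    windows = _operating_window(attributes, panel)
    unknown = sorted(set(ev["practice_id"]) - set(windows["practice_id"]))
    if unknown:
        raise InputError(f"events reference practices missing from attributes: {unknown[:10]}")
    if ev["date"].notna().any():
        data_years = (int(ev["date"].min().year), int(ev["date"].max().year))
        if panel.start_year > data_years[1] or panel.end_year < data_years[0]:
            raise ConfigurationError(
                f"panel window {panel.start_year}-{panel.end_year} outside the "
                f"data range {data_years[0]}-{data_years[1]}"
            )

    included = windows[windows["years_operating"] >= panel.min_years_operating]
    excluded = windows[windows["years_operating"] < panel.min_years_operating]
    keep = ev["practice_id"].isin(set(included["practice_id"]))
    if panel.exclude_closure_year:
        closure_year = dict(
            zip(windows.loc[windows["closes_in_window"], "practice_id"],
                windows.loc[windows["closes_in_window"], "last_year"])
        )
        closure = ev["practice_id"].map(closure_year)
        keep &= ~(closure.notna() & (ev["date"].dt.year == closure))
    filtered = ev[keep].reset_index(drop=True)

    pairs = panel_pairs(attributes, panel)
    report = {
        "n_practices_total": int(len(windows)),
        "n_practices_included": int(len(included)),
        "included_practices": included["practice_id"].tolist(),
        "excluded_practices": [
            {"practice_id": row.practice_id, "reason": f"operating {row.years_operating} year(s) "
             f"< {panel.min_years_operating}"}
            for row in excluded.itertuples()
        ],
        "n_closures_in_window": int(windows["closes_in_window"].sum()),
        "n_practice_years": int(len(pairs)),
        "n_events_in": int(len(ev)),
        "n_events_out": int(len(filtered)),
    }
    logger.info(
        "panel filters: %d/%d practices, %d practice-years, %d/%d events kept",
        report["n_practices_included"], report["n_practices_total"],
        report["n_practice_years"], report["n_events_out"], report["n_events_in"],
    )
    return filtered, report


def panel_pairs(attributes: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """The (practice_id, year) pairs forming the unbalanced annual panel."""
    windows = _operating_window(attributes, panel)
    windows = windows[windows["years_operating"] >= panel.min_years_operating]
    rows = []
    for row in windows.itertuples():
        for year in range(row.first_year, min(row.last_panel_year, panel.final_year) + 1):
            rows.append({"practice_id": row.practice_id, "year": year})
    return pd.DataFrame(rows, columns=["practice_id", "year"])


# -- pipeline ---------------------------------------------------------------

def run_pipeline(
    config: Optional[SimulationConfig] = None,
    panel: Optional[PanelDefinition] = None,
    outdir=None,
    registry: Optional[SyntheticRegistry] = None,
    min_days: int = 10,
    gap_days: int = 365,
    horizon_months: int = 12,
    censor_policy: str = "as_ongoing",
) -> dict:
    """Run the full analysis on a simulated (or supplied) registry.

    Stages: panel filters -> workforce roster -> spells -> monthly/annual/
    practice turnover (with practice-mean imputation) -> covariate profiles ->
    bivariate summaries -> the three regression specifications. When
    ``outdir`` is given, every table is written as CSV along with a
    ``manifest.json`` recording parameters and record counts; reruns with
    identical inputs reproduce byte-identical outputs.

    Returns a dict of the in-memory artifacts keyed by stage name.
    """
    if registry is None:
        if config is None:
            raise ConfigurationError("either a registry or a simulation config is required")
        config = config.validate()
        logger.info("simulating registry: %d practices, %s", config.n_practices, config.years)
        registry = generate_registry(config)
    if panel is None:
        if config is not None:
            panel = PanelDefinition(start_year=config.years[0], end_year=config.years[1] - 1)
        else:
            years = registry.events["date"].dt.year
            panel = PanelDefinition(start_year=int(years.min()), end_year=int(years.max()) - 1)
    panel = panel.validate()
    data_end = registry.events["date"].max()

    events, report = apply_panel_filters(registry.events, registry.attributes, panel)
    if events.empty:
        raise InputError("no events remain after panel filters")
    roster = build_workforce(events, min_days=min_days)
    sizes = workforce_sizes(roster)
    spells = build_spells(events, gap_days=gap_days, data_end=data_end)
    monthly = monthly_turnover(
        roster, spells, horizon_months=horizon_months,
        data_end=data_end, censor_policy=censor_policy,
    )
    monthly = monthly[monthly["month"].dt.year <= panel.final_year].reset_index(drop=True)
    pairs = panel_pairs(registry.attributes, panel)
    annual = annual_turnover(monthly, panel=pairs)
    # a practice with no regular workforce in any panel year has nothing to
    # impute from and never enters the analysis population
    observed = annual.groupby("practice_id", observed=True)["rate"].transform(
        lambda s: s.notna().any()
    )
    no_workforce = sorted(annual.loc[~observed, "practice_id"].unique())
    if no_workforce:
        logger.info("dropping %d practice(s) with no regular workforce in any "
                    "panel year: %s", len(no_workforce), no_workforce)
        annual = annual[observed].reset_index(drop=True)
    report["practices_no_regular_workforce"] = no_workforce
    report["n_practices_analyzed"] = int(annual["practice_id"].nunique())
    annual_imputed = impute_missing(annual)
    n_imputed = int(annual_imputed["imputed"].sum())
    practice = practice_average(annual_imputed)

    profiles, profile_report = build_profiles(
        registry.attributes,
        registry.registration[registry.registration["month"].dt.year <= panel.end_year],
        roster,
        practices=pd.Index(report["included_practices"]),
    )
    summaries, excluded_from_bivariate = bivariate_summary(practice, profiles)
    pooled_box = boxplot_summary(annual_imputed["rate"])
    regressions = {
        spec: fit_turnover_regression(practice, profiles, spec)
        for spec in REGRESSION_SPECS
    }
    regression_report = format_regression_report(regressions.values())
    ret_frac = return_fraction(spells)
    logger.info(
        "pipeline: %d spells, %d roster rows, %d imputed practice-years, return fraction %.3f",
        len(spells), len(roster), n_imputed, ret_frac,
    )

    artifacts = {
        "registry": registry,
        "panel_report": report,
        "roster": roster,
        "workforce_sizes": sizes,
        "spells": spells,
        "monthly": monthly,
        "annual": annual_imputed,
        "practice": practice,
        "profiles": profiles,
        "profile_report": profile_report,
        "bivariate": summaries,
        "annual_boxplot": pooled_box,
        "regressions": regressions,
        "regression_report": regression_report,
        "return_fraction": ret_frac,
        "n_imputed": n_imputed,
    }
    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir), config, panel,
                         min_days=min_days, gap_days=gap_days,
                         horizon_months=horizon_months, censor_policy=censor_policy)
    return artifacts


def _write_artifacts(artifacts, outdir: Path, config, panel, **params) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    registry: SyntheticRegistry = artifacts["registry"]
    files = {}

    def emit(name, writer, obj):
        path = outdir / name
        writer(obj, path)
        files[name] = int(len(obj)) if hasattr(obj, "__len__") else None

    emit("events.csv", write_events, registry.events)
    emit("employment.csv", write_employment, registry.employment)
    emit("registration.csv", write_registration, registry.registration)
    emit("attributes.csv", write_attributes, registry.attributes)
    emit("roster.csv", write_table, artifacts["roster"])
    emit("spells.csv", write_table, artifacts["spells"])
    emit("monthly_turnover.csv", write_table, artifacts["monthly"])
    emit("annual_turnover.csv", write_table, artifacts["annual"])
    emit("practice_turnover.csv", write_table, artifacts["practice"])
    emit("profiles.csv", write_table, artifacts["profiles"].drop(columns=["outliers"], errors="ignore"))
    emit("bivariate_summaries.csv", write_table,
         artifacts["bivariate"].assign(outliers=artifacts["bivariate"]["outliers"].map(
             lambda xs: ";".join(f"{x:g}" for x in xs))))
    (outdir / "regression_report.txt").write_text(artifacts["regression_report"] + "\n")
    files["regression_report.txt"] = None
    for spec, res in artifacts["regressions"].items():
        name = f"regression_{spec}.csv"
        write_table(res.coefficient_table().rename_axis("term").reset_index(), outdir / name)
        files[name] = int(len(res.params))

    manifest = {
        "package_version": __version__,
        "parameters": params,
        "simulation_config": config.to_dict() if config is not None else None,
        "panel": panel.to_dict(),
        "panel_report": artifacts["panel_report"],
        "profile_report": artifacts["profile_report"],
        "n_imputed_practice_years": artifacts["n_imputed"],
        "return_fraction": artifacts["return_fraction"],
        "censor_policy": params.get("censor_policy"),
        "files": files,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
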