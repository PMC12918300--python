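"""Monthly regular-workforce rosters and physician–practice spells.

The two primitives of the turnover measurement:

* the *regular workforce* of a practice in a calendar month is the set of
  physicians with consultations on at least ``min_days`` distinct days in that
  practice-month (10 by default; 15/20 used in sensitivity analyses);
* a *spell* is a maximal period of regular care provision by one physician at
  one practice, terminated by a consultation-free break of at least
  ``gap_days`` (365 by default, so leaves of up to a year do not end a spell).

Both operate on tidy event tables (one row per physician–practice–date) and
return tidy frames, the package's in-memory convention throughout.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, UndefinedValueError

__all__ = ["build_workforce", "build_spells", "return_fraction", "workforce_sizes"]

EVENT_COLUMNS = ("physician_id", "practice_id", "date")


def _coerce_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an event table: required columns, parseable dates."""
    if events is None or len(events) == 0:
        raise InputError("events table is empty")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InputError(f"events table lacks required columns {missing}")
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    if not pd.api.types.is_datetime64_any_dtype(out["date"]):
        parsed = pd.to_datetime(out["date"], errors="coerce", format="mixed")
        bad = parsed.isna() & out["date"].notna()
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy())[:10])
            raise InputError(f"unparseable dates at row indices {rows}")
        out["date"] = parsed
    if out["date"].isna().any():
        rows = list(np.flatnonzero(out["date"].isna().to_numpy())[:10])
        raise InputError(f"missing dates at row indices {rows}")
    out["date"] = out["date"].dt.normalize()
    for col in ("physician_id", "practice_id"):
        ids = out[col].astype(str)
        if (ids.str.len() == 0).any():
            raise InputError(f"empty identifiers in column {col}")
        out[col] = ids
    return out


def build_workforce(events: pd.DataFrame, min_days: int = 10) -> pd.DataFrame:
    """Monthly regular-workforce membership.

    Parameters
    ----------
    events
        Consultation events with columns ``physician_id, practice_id, date``.
        Multiple events on the same day count as a single day.
    min_days
        Minimum number of distinct consultation days in a practice-month for a
        physician to belong to that month's regular workforce (inclusive).

    Returns
    -------
    DataFrame with one row per qualifying (practice, month, physician):
    columns ``practice_id, month, physician_id, n_days``. Months in which no
    physician qualifies are simply absent ("no regular workforce").
    """
    if not (isinstance(min_days, (int, np.integer)) and min_days >= 1):
        raise ParameterError(f"min_days must be an integer >= 1, got {min_days!r}")
    ev = _coerce_events(events)
    ev = ev.drop_duplicates(subset=["physician_id", "practice_id", "date"])
    ev["month"] = ev["date"].dt.to_period("M")
    counts = (
        ev.groupby(["practice_id", "month", "physician_id"], observed=True)
        .size()
        .rename("n_days")
        .reset_index()
    )
    roster = counts[counts["n_days"] >= int(min_days)].reset_index(drop=True)
    return roster.sort_values(["practice_id", "month", "physician_id"], ignore_index=True)


def workforce_sizes(roster: pd.DataFrame) -> pd.DataFrame:
    """Collapse a roster to per-(practice, month) workforce sizes."""
    return (
        roster.groupby(["practice_id", "month"], observed=True)["physician_id"]
        .nunique()
        .rename("size")
        .reset_index()
    )


def build_spells(
    events: pd.DataFrame,
    gap_days: int = 365,
    data_end: Optional[pd.Timestamp] = None,
) -> pd.DataFrame:
    """Segment each physician–practice event history into spells.

    Sorted distinct event dates are split wherever the break between
    consecutive consultations is at least ``gap_days`` (inclusive: a break of
    exactly ``gap_days`` ends the spell). Spell duration is the number of days
    between the first and the last consultation. A spell is flagged
    ``censored`` when its last consultation lies within ``gap_days`` of
    ``data_end``, i.e. when its termination cannot be confirmed.

    Returns a DataFrame with columns ``physician_id, practice_id, first_date,
    last_date, duration_days, n_events, censored``.
    """
    if not (isinstance(gap_days, (int, np.integer)) and gap_days >= 1):
        raise ParameterError(f"gap_days must be an integer >= 1, got {gap_days!r}")
    ev = _coerce_events(events)
    max_date = ev["date"].max()
    if data_end is None:
        data_end = max_date
    else:
        data_end = pd.Timestamp(data_end).normalize()
        if max_date > data_end:
            raise InputError(
                f"events after data_end ({data_end.date()}): last event {max_date.date()}"
            )
    ev = ev.drop_duplicates(subset=["physician_id", "practice_id", "date"])
    ev = ev.sort_values(["physician_id", "practice_id", "date"], kind="mergesort")
    same_pair = (
        ev["physician_id"].eq(ev["physician_id"].shift())
        & ev["practice_id"].eq(ev["practice_id"].shift())
    )
    gap = ev["date"].diff().dt.days
    new_spell = ~same_pair | (gap >= gap_days)
    ev["spell_id"] = new_spell.cumsum()
    spells = (
        ev.groupby("spell_id", observed=True)
        .agg(
            physician_id=("physician_id", "first"),
            practice_id=("practice_id", "first"),
            first_date=("date", "min"),
            last_date=("date", "max"),
            n_events=("date", "size"),
        )
        .reset_index(drop=True)
    )
    spells["duration_days"] = (spells["last_date"] - spells["first_date"]).dt.days
    spells["censored"] = (data_end - spells["last_date"]).dt.days < gap_days
    cols = ["physician_id", "practice_id", "first_date", "last_date",
            "duration_days", "n_events", "censored"]
    return spells.loc[:, cols].sort_values(
        ["physician_id", "practice_id", "first_date"], ignore_index=True
    )


def return_fraction(spells: pd.DataFrame) -> float:
    """Fraction of physicians who ever returned to a practice they had left.

    A "return" is a second spell of the same physician at the same practice
    (possible only after a break of at least the gap threshold). The
    denominator is the number of distinct physicians in ``spells``.
    """
    if spells is None or len(spells) == 0:
        raise UndefinedValueError("return fraction is undefined for an empty spell table")
    per_pair = spells.groupby(["physician_id", "practice_id"], observed=True).size()
    returners = per_pair[per_pair >= 2].reset_index()["physician_id"].nunique()
    return returners / spells["physician_id"].nunique()
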