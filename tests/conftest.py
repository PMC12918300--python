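"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (pure-Python loops over small inputs)
and independent of the vectorised implementations they check.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from gp_turnover import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def tiny_config():
    """A small, fast registry configuration for structural tests."""
    return SimulationConfig(
        n_practices=8,
        years=(2010, 2013),
        seed=11,
        p_open_close=(0.2, 0.15),
    )


def random_events(rng, n_events=40, n_physicians=4, n_practices=2,
                  start="2010-01-01", span_days=2200) -> pd.DataFrame:
    """A random small event table (duplicates allowed on purpose)."""
    start_ts = pd.Timestamp(start)
    return pd.DataFrame({
        "physician_id": [f"d{i}" for i in rng.integers(0, n_physicians, n_events)],
        "practice_id": [f"p{i}" for i in rng.integers(0, n_practices, n_events)],
        "date": start_ts + pd.to_timedelta(rng.integers(0, span_days, n_events), unit="D"),
    })


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_workforce(events: pd.DataFrame, min_days: int) -> set:
    """Set of (practice, 'YYYY-MM', physician) with >= min_days distinct days."""
    days = defaultdict(set)
    for row in events.itertuples():
        date = pd.Timestamp(row.date)
        days[(str(row.practice_id), f"{date.year:04d}-{date.month:02d}", str(row.physician_id))].add(
            date.normalize()
        )
    return {key for key, ds in days.items() if len(ds) >= min_days}


def oracle_spells(events: pd.DataFrame, gap_days: int) -> list:
    """Linear-scan segmentation: [(physician, practice, first, last), ...]."""
    by_pair = defaultdict(set)
    for row in events.itertuples():
        by_pair[(str(row.physician_id), str(row.practice_id))].add(pd.Timestamp(row.date).normalize())
    out = []
    for (phys, prac), dates in by_pair.items():
        dates = sorted(dates)
        first = prev = dates[0]
        for d in dates[1:]:
            if (d - prev).days >= gap_days:
                out.append((phys, prac, first, prev))
                first = d
            prev = d
        out.append((phys, prac, first, prev))
    return sorted(out)


def oracle_monthly_turnover(workforce, spells, horizon, data_end, censor_policy="as_ongoing"):
    """Direct enumeration of the within-horizon turnover rate per practice-month."""
    spell_list = list(spells.itertuples())
    results = {}
    for row in workforce.itertuples():
        month = row.month if isinstance(row.month, pd.Period) else pd.Period(row.month, "M")
        hz_end = (month + horizon).end_time.normalize()
        if hz_end > data_end:
            continue
        m_start, m_end = month.start_time, month.end_time.normalize()
        covering = [
            s for s in spell_list
            if s.physician_id == row.physician_id and s.practice_id == row.practice_id
            and s.first_date <= m_end and s.last_date >= m_start
        ]
        assert len(covering) == 1
        s = covering[0]
        ended = s.last_date <= hz_end
        if censor_policy == "as_ongoing" and s.censored:
            ended = False
        if censor_policy == "exclude" and s.censored:
            continue
        key = (row.practice_id, month)
        results.setdefault(key, []).append(ended)
    return {
        key: (100.0 * sum(flags) / len(flags), len(flags))
        for key, flags in results.items()
    }


def oracle_tercile(values) -> list:
    """Rank-based tercile codes, ties to the lower tercile; 0 for missing."""
    vals = list(values)
    present = sorted(v for v in vals if v == v)  # NaN-safe
    n = len(present)
    codes = []
    for v in vals:
        if v != v:
            codes.append(0)
            continue
        min_rank = 1 + sum(1 for w in present if w < v)
        codes.append(int(3 * (min_rank - 1) // n) + 1)
    return codes


def oracle_sandwich_hc1(X: np.ndarray, y: np.ndarray):
    """Explicit HC1 sandwich: (X'X)^-1 X' diag(e^2) X (X'X)^-1 * n/(n-k)."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    meat = X.T @ (X * (e ** 2)[:, None])
    cov = XtX_inv @ meat @ XtX_inv * (n / (n - k))
    return beta, np.sqrt(np.diag(cov))


def oracle_boxplot(x):
    """Direct implementation of the adjacent-value whisker rule."""
    x = np.sort(np.asarray(x, dtype=float))
    p25, med, p75 = np.percentile(x, [25, 50, 75])
    iqr = p75 - p25
    lo, hi = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    return {
        "median": med, "p25": p25, "p75": p75,
        "lower_adjacent": inside.min(), "upper_adjacent": inside.max(),
        "outliers": sorted(x[(x < lo) | (x > hi)].tolist()),
    }


def events_from_dates(physician, practice, dates) -> pd.DataFrame:
    return pd.DataFrame({
        "physician_id": physician,
        "practice_id": practice,
        "date": pd.to_datetime(list(dates)),
    })
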