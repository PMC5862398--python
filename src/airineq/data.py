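"""Tabular schemas, readers, and the three data-preparation rules.

All three inputs are comma-separated UTF-8 text with a header row:

* households: household_id, year, state_id, county_id, market_income,
  member_age_cohorts ('|'-joined cohort indices 1..15), race,
  census_division
* mortality: county_id, age_cohort, rate, death_count
* monitors: monitor_id, county_id, pollutant (PM25 or O3), period_value

Preparation rules applied before any damage is computed:

* top-coding — within each state, incomes strictly above the state's 99.5th
  percentile are replaced by the mean of those incomes (the disclosure rule
  applied to public-use survey income);
* reliability filtering — mortality cells estimated from fewer than 20
  deaths are dropped as unreliable;
* monitor aggregation — monitor readings are averaged (unweighted) to a
  single period-mean concentration per county and pollutant; counties with
  no monitor for a pollutant are simply absent, and downstream stages
  restrict the analysis to monitored counties.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HOUSEHOLD_COLUMNS",
    "MORTALITY_COLUMNS",
    "MONITOR_COLUMNS",
    "POLLUTANTS",
    "RACES",
    "N_COHORTS",
    "read_households",
    "read_mortality",
    "read_monitors",
    "apply_topcoding",
    "filter_reliable_mortality",
    "aggregate_monitors",
]

HOUSEHOLD_COLUMNS = [
    "household_id",
    "year",
    "state_id",
    "county_id",
    "market_income",
    "member_age_cohorts",
    "race",
    "census_division",
]
MORTALITY_COLUMNS = ["county_id", "age_cohort", "rate", "death_count"]
MONITOR_COLUMNS = ["monitor_id", "county_id", "pollutant", "period_value"]

POLLUTANTS = ("PM25", "O3")
RACES = ("white", "black", "hispanic", "asian", "other")
N_COHORTS = 15
RELIABILITY_MIN_DEATHS = 20


def _check_header(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _valid_cohorts(value: str) -> bool:
    try:
        parts = [int(v) for v in str(value).split("|") if v != ""]
    except ValueError:
        return False
    return len(parts) >= 1 and all(1 <= p <= N_COHORTS for p in parts)


def read_households(path: str | Path) -> pd.DataFrame:
    """Read and validate the household table.

    Malformed rows (unparseable income, cohort index outside 1..15, no
    members) are rejected and logged with their line numbers; a missing
    required column is a hard error.  Returns the validated records.
    """
    df = pd.read_csv(path, dtype={"state_id": str, "county_id": str})
    _check_header(df, HOUSEHOLD_COLUMNS, path)
    if df.empty:
        logger.warning("%s: empty household file (header only)", path)
        return df

    income = pd.to_numeric(df["market_income"], errors="coerce")
    bad_income = income.isna()
    bad_cohorts = ~df["member_age_cohorts"].map(_valid_cohorts)
    bad = bad_income | bad_cohorts
    if bad.any():
        # +2: header line and 1-based numbering
        for i in df.index[bad]:
            reason = "unparseable income" if bad_income[i] else "invalid member cohorts"
            logger.warning("%s: line %d rejected (%s)", path, i + 2, reason)
        df = df[~bad].copy()
    df["market_income"] = pd.to_numeric(df["market_income"])
    df["year"] = df["year"].astype(int)
    return df.reset_index(drop=True)


def read_mortality(path: str | Path) -> pd.DataFrame:
    """Read the county x age-cohort mortality table (unfiltered)."""
    df = pd.read_csv(path, dtype={"county_id": str})
    _check_header(df, MORTALITY_COLUMNS, path)
    if df.empty:
        return df
    bad = (
        pd.to_numeric(df["rate"], errors="coerce").isna()
        | (df["rate"] <= 0)
        | (df["rate"] >= 1)
    )
    if bad.any():
        for i in df.index[bad]:
            logger.warning("%s: line %d rejected (rate outside (0,1))", path, i + 2)
        df = df[~bad].copy()
    df["age_cohort"] = df["age_cohort"].astype(int)
    df["death_count"] = df["death_count"].astype(int)
    return df.reset_index(drop=True)


def read_monitors(path: str | Path) -> pd.DataFrame:
    """Read the monitor-reading table."""
    df = pd.read_csv(path, dtype={"county_id": str, "monitor_id": str})
    _check_header(df, MONITOR_COLUMNS, path)
    if df.empty:
        return df
    bad = pd.to_numeric(df["period_value"], errors="coerce").isna() | (
        df["period_value"] < 0
    )
    unknown = ~df["pollutant"].isin(POLLUTANTS)
    for i in df.index[bad | unknown]:
        logger.warning("%s: line %d rejected (bad reading)", path, i + 2)
    return df[~(bad | unknown)].reset_index(drop=True)


def apply_topcoding(
    incomes: pd.Series | np.ndarray,
    states: pd.Series | np.ndarray,
    q: float = 0.995,
) -> np.ndarray:
    """Top-code incomes within each state at the q-quantile.

    Within each state, every income strictly above that state's q-quantile
    (nearest-rank, i.e. type-1, quantile) is replaced by the mean of all such
    incomes; everything else is unchanged.  Mean replacement preserves the
    within-state income total exactly, so state and national means are
    unaffected while top-tail dispersion is removed.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    y = np.asarray(incomes, dtype=float).copy()
    s = np.asarray(states)
    if y.size != s.size:
        raise ValueError("incomes and states must have equal length")
    n_replaced = 0
    for state in np.unique(s):
        mask = s == state
        vals = y[mask]
        if vals.size == 0:
            raise ValueError(f"state group {state!r} is empty")
        # nearest-rank quantile: k-th smallest with k = ceil(q * n)
        k = int(np.ceil(q * vals.size))
        cut = np.sort(vals)[k - 1]
        top = vals > cut
        if top.any():
            vals[top] = vals[top].mean()
            y[mask] = vals
            n_replaced += int(top.sum())
    if n_replaced:
        logger.info("apply_topcoding: %d incomes replaced", n_replaced)
    return y


def filter_reliable_mortality(
    table: pd.DataFrame, min_deaths: int = RELIABILITY_MIN_DEATHS
) -> pd.DataFrame:
    """Drop mortality cells estimated from fewer than ``min_deaths`` deaths.

    Idempotent; the count of removed rows is logged.
    """
    if table.empty:
        return table
    keep = table["death_count"] >= min_deaths
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_reliable_mortality: %d unreliable cells removed (< %d deaths)",
            n_removed,
            min_deaths,
        )
    return table[keep].reset_index(drop=True)


def aggregate_monitors(readings: pd.DataFrame) -> pd.DataFrame:
    """Average monitor readings to county-level period-mean concentrations.

    Unweighted mean over all monitors of a pollutant in a county; counties
    without any monitor for a pollutant have no row for it, and downstream
    stages drop households in counties lacking either pollutant.

    Returns columns county_id, pollutant, concentration; order-invariant in
    the readings.
    """
    if readings.empty:
        return pd.DataFrame(columns=["county_id", "pollutant", "concentration"])
    out = (
        readings.groupby(["county_id", "pollutant"], sort=True)["period_value"]
        .mean()
        .rename("concentration")
        .reset_index()
    )
    return out
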