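"""Pipeline orchestration: prepare -> damages -> inequality, scenario grid.

A scenario fixes the concentration-response source per pollutant, the VSL
mode, and the analysis unit, then runs the full chain and returns a result
bundle: market / externality / adjusted Ginis with bootstrap SEs, quintile
shares under both income definitions, the pollutant source-share
decomposition, group decompositions by race and census division, and run
metadata (every parameter plus input checksums) so each number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import damage as dmg
from . import inequality as ineq
from .data import (
    aggregate_monitors,
    apply_topcoding,
    filter_reliable_mortality,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "prepare_inputs", "run_scenario", "multi_year_report"]

CR_SOURCES: Mapping[str, dmg.ConcentrationResponse] = {
    "krewski": dmg.KREWSKI_PM25,
    "lepeule": dmg.LEPEULE_PM25,
    "bell": dmg.BELL_O3,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the sensitivity grid.

    ``vsl_mode``: 'uniform' (central VSL), 'uniform_alternative' (low VSL),
    or 'income_varying' (constant-elasticity scaling by household income).
    ``unit``: 'household' deduplicates nothing (one row per household);
    'individual' replicates each household row once per member, so each
    person carries the household income and damage.
    """

    name: str = "default"
    pm25_source: str = "krewski"
    o3_source: str = "bell"
    vsl_mode: str = "uniform"
    income_elasticity: float = 0.4
    base_vsl: float = 10.2e6
    alt_vsl: float = 3.3e6
    unit: str = "household"
    bootstrap_B: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pm25_source not in CR_SOURCES or self.o3_source not in CR_SOURCES:
            raise ValueError(
                f"unknown concentration-response source in scenario {self.name!r}"
            )
        if CR_SOURCES[self.pm25_source].pollutant != "PM25":
            raise ValueError(f"{self.pm25_source!r} is not a PM2.5 source")
        if CR_SOURCES[self.o3_source].pollutant != "O3":
            raise ValueError(f"{self.o3_source!r} is not an O3 source")
        if self.vsl_mode not in {"uniform", "uniform_alternative", "income_varying"}:
            raise ValueError(f"unknown vsl_mode {self.vsl_mode!r}")
        if self.unit not in {"household", "individual"}:
            raise ValueError(f"unknown analysis unit {self.unit!r}")


def prepare_inputs(
    households: pd.DataFrame,
    mortality: pd.DataFrame,
    monitors: pd.DataFrame,
    topcode_q: float = 0.995,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the three preparation rules.

    Top-codes incomes within state at the 99.5th percentile, drops
    unreliable mortality cells (< 20 deaths), and averages monitors to
    county-level concentrations.
    """
    hh = households.copy()
    hh["market_income"] = apply_topcoding(
        hh["market_income"], hh["state_id"], q=topcode_q
    )
    mort = filter_reliable_mortality(mortality)
    conc = aggregate_monitors(monitors)
    logger.info(
        "prepare_inputs: %d households, %d reliable mortality cells, "
        "%d county-pollutant concentrations",
        len(hh),
        len(mort),
        len(conc),
    )
    return hh, mort, conc


def _vsl_schedule(spec: ScenarioSpec) -> dmg.VSLSchedule:
    return dmg.VSLSchedule(
        base_vsl=spec.base_vsl,
        alt_vsl=spec.alt_vsl,
        income_elasticity=spec.income_elasticity,
        mode=spec.vsl_mode,
    )


def _to_unit(table: pd.DataFrame, unit: str) -> pd.DataFrame:
    if unit == "household":
        return table
    counts = table["member_age_cohorts"].str.count(r"\|") + 1
    return table.loc[table.index.repeat(counts)].reset_index(drop=True)


def run_scenario(
    spec: ScenarioSpec,
    households: pd.DataFrame,
    mortality: pd.DataFrame,
    concentrations: pd.DataFrame,
) -> dict:
    """Run one scenario on prepared inputs and return the result bundle.

    Inputs must already be prepared (top-coded, reliability-filtered,
    county-aggregated); see :func:`prepare_inputs`.
    """
    crs = {"PM25": CR_SOURCES[spec.pm25_source], "O3": CR_SOURCES[spec.o3_source]}
    vsl = _vsl_schedule(spec)
    ledger = dmg.household_damage(households, mortality, concentrations, crs, vsl)
    table = dmg.adjusted_income_table(ledger)
    if spec.unit == "individual":
        merged = table.merge(
            households[["household_id", "member_age_cohorts"]], on="household_id"
        )
        table = _to_unit(merged, "individual").drop(columns="member_age_cohorts")

    B, seed = spec.bootstrap_B, spec.seed
    results: dict = {"scenario": spec.name, "n": len(table)}
    for label, col in (
        ("market", "market_income"),
        ("externality", "damage"),
        ("adjusted", "adjusted_income"),
    ):
        vals = table[col].to_numpy(dtype=float)
        g = ineq.gini(vals)
        se = ineq.bootstrap_se(vals, B=B, seed=seed) if B else None
        results[f"gini_{label}"] = g.estimate
        results[f"se_{label}"] = se
    results["ratio_adjusted_market"] = (
        results["gini_adjusted"] / results["gini_market"]
    )
    results["source_shares"] = ineq.source_shares(
        table[["damage_PM25", "damage_O3"]].rename(
            columns={"damage_PM25": "PM25", "damage_O3": "O3"}
        )
    ).to_dict()
    results["quintile_shares_market"] = ineq.quintile_shares(
        table["market_income"], bootstrap_B=B, seed=seed
    )
    results["quintile_shares_adjusted"] = ineq.quintile_shares(
        table["adjusted_income"], bootstrap_B=B, seed=seed
    )
    results["share_negative_adjusted"] = float(
        (table["adjusted_income"] < 0).mean()
    )
    for group in ("race", "census_division"):
        if group in table.columns:
            results[f"by_{group}"] = ineq.group_ginis(
                table, group, bootstrap_B=min(B, 50), seed=seed
            )
    results["table"] = table
    results["metadata"] = {
        "scenario": asdict(spec),
        "beta": ledger.attrs["beta"],
        "vsl": ledger.attrs["vsl"],
        "exclusions": ledger.attrs["exclusions"],
        "bootstrap_B": B,
        "tie_rule": "mid-rank empirical CDF, 1/n covariance",
        "input_checksums": {
            "households": _frame_checksum(households),
            "mortality": _frame_checksum(mortality),
            "concentrations": _frame_checksum(concentrations),
        },
        "config_hash": _dict_checksum(asdict(spec)),
    }
    return results


def _frame_checksum(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _dict_checksum(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def format_table1(results: dict) -> pd.DataFrame:
    """One Gini-summary row per scenario/year (machine-readable columns)."""
    rows = []
    for r in results if isinstance(results, list) else [results]:
        rows.append(
            {
                "scenario": r["scenario"],
                "obs": r["n"],
                "gini_market": r["gini_market"],
                "se_market": r["se_market"],
                "gini_externality": r["gini_externality"],
                "se_externality": r["se_externality"],
                "gini_adjusted": r["gini_adjusted"],
                "se_adjusted": r["se_adjusted"],
                "share_PM25": r["source_shares"]["PM25"],
                "share_O3": r["source_shares"]["O3"],
                "ratio_adjusted_market": r["ratio_adjusted_market"],
            }
        )
    return pd.DataFrame(rows)


def multi_year_report(year_results: Mapping[int, dict]) -> pd.DataFrame:
    """Gini-summary panel per year plus year-over-year deltas.

    The adjusted/market ratio is computed from the unrounded Ginis of each
    year's result bundle.  With a single year, no delta columns are added.
    """
    if not year_results:
        raise ValueError("need at least one year of results")
    rows = []
    for year in sorted(year_results):
        r = year_results[year]
        row = format_table1(r).iloc[0].to_dict()
        row["year"] = year
        rows.append(row)
    panel = pd.DataFrame(rows).set_index("year")
    if len(panel) > 1:
        for col in ("gini_market", "gini_externality", "gini_adjusted"):
            panel[f"delta_{col}"] = panel[col].diff()
    return panel.reset_index()
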