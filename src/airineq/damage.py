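"""Attributable mortality risk, monetized damage, and adjusted income.

The damage model is the standard health-impact-assessment chain used in
regulatory benefit analysis of air pollution:

1. A log-linear concentration-response function converts an ambient
   concentration C of a pollutant into the share of baseline mortality risk
   attributable to exposure,

       M = gamma * (1 - exp(-beta * C)),

   where gamma is the all-cause baseline mortality rate of the person's age
   cohort in their county and beta the per-unit log-risk slope from the
   epidemiological literature.

2. The risk is monetized with a value of a statistical life (VSL):
   D = sum over pollutants of VSL * M.  The VSL is either uniform across the
   population or scaled by household income with a constant elasticity.

3. Adjusted income is market household income minus the household's total
   damage; it may be negative for poor, heavily exposed households.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationResponse",
    "VSLSchedule",
    "beta_from_relative_risk",
    "attributable_risk",
    "monetize_person",
    "adjust_vsl_income",
    "household_damage",
    "adjusted_income_table",
    "KREWSKI_PM25",
    "LEPEULE_PM25",
    "BELL_O3",
]


def beta_from_relative_risk(rr: float, delta: float) -> float:
    """Convert a published relative risk per concentration increment to beta.

    A cohort study reporting relative risk ``rr`` for a ``delta``-unit
    increase in concentration under a log-linear model implies
    beta = ln(rr) / delta per concentration unit.
    """
    if rr < 1.0:
        raise ValueError(f"relative risk must be >= 1, got {rr}")
    if delta <= 0:
        raise ValueError(f"increment must be positive, got {delta}")
    return math.log(rr) / delta


@dataclass(frozen=True)
class ConcentrationResponse:
    """Log-linear concentration-response slope for one pollutant.

    ``beta`` has units 1/(ug/m3) for PM2.5 and 1/ppb for O3;
    ``source_label`` names the cohort study the slope is drawn from.
    """

    pollutant: str
    beta: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


# Default slopes, derived from the relative risks published by the cited
# cohort studies: long-term all-cause mortality RR per 10 ug/m3 PM2.5 of
# 1.06 (Krewski et al.) and 1.14 (LePeule et al.); short-term mortality RR
# per 10 ppb O3 of 1.0052 (Bell et al.).
KREWSKI_PM25 = ConcentrationResponse(
    "PM25", beta_from_relative_risk(1.06, 10.0), "krewski"
)
LEPEULE_PM25 = ConcentrationResponse(
    "PM25", beta_from_relative_risk(1.14, 10.0), "lepeule"
)
BELL_O3 = ConcentrationResponse("O3", beta_from_relative_risk(1.0052, 10.0), "bell")


@dataclass(frozen=True)
class VSLSchedule:
    """Value of a statistical life, uniform or income-varying.

    ``base_vsl`` is the central estimate (USD, $10.2M for 2011 in the default
    configuration); ``alt_vsl`` the lower alternative ($3.3M).  In
    ``income_varying`` mode the household's VSL is
    base * (income / reference_income) ** income_elasticity, with households
    of non-positive income receiving the base (the power law is undefined
    there).  ``per_year`` optionally overrides the base VSL by data year,
    standing in for nominal-income escalation of the VSL over the panel.
    """

    base_vsl: float = 10.2e6
    alt_vsl: float = 3.3e6
    income_elasticity: float = 0.4
    mode: str = "uniform"
    reference_income: float | None = None
    per_year: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_vsl <= 0:
            raise ValueError("base_vsl must be positive")
        if self.income_elasticity < 0:
            raise ValueError("income elasticity must be non-negative")
        if self.mode not in {"uniform", "uniform_alternative", "income_varying"}:
            raise ValueError(f"unknown VSL mode {self.mode!r}")

    def vsl_for(self, income: float | np.ndarray, year: int | None = None) -> np.ndarray:
        """Vectorized VSL for a household income (and optionally a year)."""
        base = self.per_year.get(year, self.base_vsl) if year is not None else self.base_vsl
        if self.mode == "uniform_alternative":
            base = self.alt_vsl
        income = np.asarray(income, dtype=float)
        if self.mode != "income_varying":
            return np.full_like(income, base, dtype=float)
        ref = self.reference_income
        if ref is None or ref <= 0:
            raise ValueError(
                "income_varying mode requires a positive reference_income "
                "(set it to the analysis-sample mean income)"
            )
        out = np.where(
            income > 0,
            base * np.power(np.maximum(income, 1e-300) / ref, self.income_elasticity),
            base,
        )
        return out


def attributable_risk(
    gamma: float | np.ndarray,
    beta: float,
    conc: float | np.ndarray,
) -> float | np.ndarray:
    """Mortality risk attributable to exposure: M = gamma * (1 - exp(-beta*C)).

    M lies in [0, gamma) and increases in each argument; for beta*C << 1 it
    linearizes to gamma*beta*C.
    """
    gamma_arr = np.asarray(gamma, dtype=float)
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(gamma_arr <= 0) or np.any(gamma_arr >= 1):
        raise ValueError("baseline mortality rate must lie in (0, 1)")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be non-negative")
    m = gamma_arr * (-np.expm1(-beta * conc_arr))
    if np.isscalar(gamma) and np.isscalar(conc):
        return float(m)
    return m


def monetize_person(
    risks: Mapping[str, float],
    vsl: float,
) -> float:
    """Monetary damage for one person: D = sum over pollutants of VSL * M."""
    if vsl <= 0:
        raise ValueError(f"VSL must be positive, got {vsl}")
    for p, m in risks.items():
        if m < 0:
            raise ValueError(f"risk for {p} is negative: {m}")
    return float(vsl * sum(risks.values()))


def adjust_vsl_income(
    base_vsl: float,
    eta: float,
    income: float,
    reference_income: float,
) -> float:
    """Income-varying VSL: base * (income / reference) ** eta.

    Households with non-positive income receive the base VSL.
    """
    if base_vsl <= 0:
        raise ValueError("base_vsl must be positive")
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if reference_income <= 0:
        raise ValueError("reference income must be positive")
    if income <= 0:
        return base_vsl
    return float(base_vsl * (income / reference_income) ** eta)


def _pivot_mortality(mortality: pd.DataFrame) -> pd.Series:
    """(county_id, age_cohort) -> rate lookup from a mortality table."""
    return mortality.set_index(["county_id", "age_cohort"])["rate"]


def _pivot_concentration(conc: pd.DataFrame) -> pd.DataFrame:
    """county_id -> one column per pollutant, NaN where unmonitored."""
    return conc.pivot_table(
        index="county_id", columns="pollutant", values="concentration"
    )


def household_damage(
    households: pd.DataFrame,
    mortality: pd.DataFrame,
    concentrations: pd.DataFrame,
    crs: Mapping[str, ConcentrationResponse],
    vsl: VSLSchedule,
    year: int | None = None,
) -> pd.DataFrame:
    """Per-household monetized damage by pollutant and adjusted income.

    Each member's attributable risk uses the member's age-cohort baseline
    mortality rate in the household's county and the county's period-mean
    concentrations; the household's damage is the sum over members and
    pollutants of VSL * M, and adjusted income is market income minus damage.

    Households in counties missing a concentration for either pollutant, or
    missing the mortality cell for any member's cohort (e.g. removed by the
    reliability filter), are excluded; the counts are logged and attached to
    the result as ``DataFrame.attrs["exclusions"]``.

    ``households`` must have columns household_id, county_id, market_income,
    member_age_cohorts (list of ints or '|'-joined string).  Returns one row
    per retained household with damage_PM25, damage_O3, damage,
    adjusted_income, and pass-through demographics.
    """
    pollutants = list(crs)
    conc_wide = _pivot_concentration(concentrations)
    rate_lookup = _pivot_mortality(mortality)

    hh = households.copy()
    cohorts = hh["member_age_cohorts"].apply(_parse_cohorts)

    # explode to member level for vectorized lookups
    members = pd.DataFrame(
        {
            "household_id": hh["household_id"].repeat(cohorts.str.len()),
            "county_id": hh["county_id"].repeat(cohorts.str.len()),
            "age_cohort": np.concatenate(cohorts.to_numpy()),
        }
    )
    idx = pd.MultiIndex.from_frame(members[["county_id", "age_cohort"]])
    members["gamma"] = rate_lookup.reindex(idx).to_numpy()

    # households with any member in a missing mortality cell
    missing_cell = members.loc[members["gamma"].isna(), "household_id"].unique()
    # households in counties without both pollutant concentrations
    conc_ok = conc_wide.reindex(columns=pollutants).dropna()
    unmonitored = ~hh["county_id"].isin(conc_ok.index)
    n_unmonitored = int(unmonitored.sum())
    keep_ids = set(hh.loc[~unmonitored, "household_id"]) - set(missing_cell)
    n_missing_cell = hh["household_id"].isin(missing_cell).sum()
    if n_unmonitored or n_missing_cell:
        logger.info(
            "household_damage: excluded %d households in unmonitored counties, "
            "%d with missing mortality cells",
            n_unmonitored,
            int(n_missing_cell),
        )

    members = members[members["household_id"].isin(keep_ids)]
    hh = hh[hh["household_id"].isin(keep_ids)].reset_index(drop=True)

    # per-household VSL (income-varying uses household income for every member)
    if vsl.mode == "income_varying" and vsl.reference_income is None:
        vsl = VSLSchedule(
            base_vsl=vsl.base_vsl,
            alt_vsl=vsl.alt_vsl,
            income_elasticity=vsl.income_elasticity,
            mode=vsl.mode,
            reference_income=float(hh["market_income"].mean()),
            per_year=vsl.per_year,
        )
    hh_vsl = pd.Series(
        vsl.vsl_for(hh["market_income"].to_numpy(), year=year),
        index=hh["household_id"],
    )
    members_vsl = hh_vsl.reindex(members["household_id"]).to_numpy()

    for p in pollutants:
        c = conc_ok[p].reindex(members["county_id"]).to_numpy()
        m_risk = members["gamma"].to_numpy() * (-np.expm1(-crs[p].beta * c))
        members[f"damage_{p}"] = members_vsl * m_risk

    dmg_cols = [f"damage_{p}" for p in pollutants]
    hh_damage = members.groupby("household_id", sort=False)[dmg_cols].sum()

    out = hh.merge(hh_damage, left_on="household_id", right_index=True)
    out["damage"] = out[dmg_cols].sum(axis=1)
    out["adjusted_income"] = out["market_income"] - out["damage"]
    out.attrs["exclusions"] = {
        "unmonitored_county": n_unmonitored,
        "missing_mortality_cell": int(n_missing_cell),
    }
    out.attrs["vsl"] = {
        "mode": vsl.mode,
        "base_vsl": vsl.base_vsl,
        "reference_income": vsl.reference_income,
    }
    out.attrs["beta"] = {p: crs[p].beta for p in pollutants}
    return out


def _parse_cohorts(value) -> np.ndarray:
    if isinstance(value, str):
        parts = [int(v) for v in value.split("|") if v]
    else:
        parts = [int(v) for v in value]
    if not parts:
        raise ValueError("household must have at least one member")
    return np.asarray(parts, dtype=int)


def adjusted_income_table(damages: pd.DataFrame) -> pd.DataFrame:
    """Analysis table of market income, damages, and adjusted income.

    Thin projection of :func:`household_damage` output to the columns the
    inequality stage consumes; reports the share of households with negative
    adjusted income (logged and exposed via ``attrs``).
    """
    cols = [
        c
        for c in (
            "household_id",
            "year",
            "state_id",
            "county_id",
            "race",
            "census_division",
            "market_income",
            "damage_PM25",
            "damage_O3",
            "damage",
            "adjusted_income",
        )
        if c in damages.columns
    ]
    out = damages[cols].copy()
    share_neg = float((out["adjusted_income"] < 0).mean())
    logger.info(
        "adjusted_income_table: %.2f%% of households have negative adjusted income",
        100 * share_neg,
    )
    out.attrs["share_negative_adjusted"] = share_neg
    return out
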