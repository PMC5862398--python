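"""Synthetic household, mortality, and monitor tables.

The real analysis inputs — survey household microdata, county mortality
files, and ambient monitor readings — are restricted or bulky downloads, so
this module generates tables with the same statistical structure:

* right-skewed lognormal household incomes with race-level shifts and a
  county-level component (later top-coded by the preparation stage);
* county PM2.5 / O3 levels negatively correlated with county mean income
  (poorer counties are more polluted);
* baseline all-cause mortality rates per county and 15-level age cohort,
  strongly increasing in age and decreasing in county income, each cell
  carrying a Poisson death count so the reliability filter has something
  real to censor;
* 1-3 monitors per county and pollutant whose readings scatter around the
  county-level concentration.

The dependence structure is deliberately simple: linear-in-z-score
perturbations on the log scale, enough to reproduce the qualitative
gradients (exposure inequality mild, baseline-risk inequality severe,
pollution anti-correlated with income) without a copula machinery the
downstream statistics do not need.

Everything is deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .data import N_COHORTS, POLLUTANTS, RACES

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "simulate_population", "write_tables", "load_config"]


# All-cause death rates per person-year for 15 five/ten-year age cohorts
# (0-4 ... 65-74, 75+), smoothed to be non-decreasing in age as the config
# invariant requires.
_DEFAULT_COHORT_RATES = (
    2.0e-4,
    2.0e-4,
    2.5e-4,
    5.0e-4,
    8.0e-4,
    1.0e-3,
    1.2e-3,
    1.6e-3,
    2.2e-3,
    3.2e-3,
    4.8e-3,
    7.0e-3,
    1.05e-2,
    2.2e-2,
    8.0e-2,
)

# Age-cohort population shares, roughly a mature industrialized pyramid.
_DEFAULT_COHORT_SHARES = (
    0.061,
    0.064,
    0.065,
    0.066,
    0.070,
    0.069,
    0.067,
    0.065,
    0.063,
    0.064,
    0.067,
    0.066,
    0.060,
    0.088,
    0.065,
)

_DEFAULT_RACE_MIXTURE = {
    "white": 0.64,
    "black": 0.12,
    "hispanic": 0.16,
    "asian": 0.05,
    "other": 0.03,
}

_DEFAULT_RACE_SHIFT = {
    "white": 0.0,
    "black": -0.45,
    "hispanic": -0.35,
    "asian": 0.15,
    "other": -0.20,
}

_DEFAULT_HH_SIZE_PROBS = (0.28, 0.34, 0.15, 0.13, 0.06, 0.04)

_DIVISIONS = (
    "new_england",
    "middle_atlantic",
    "east_north_central",
    "west_north_central",
    "south_atlantic",
    "east_south_central",
    "west_south_central",
    "mountain",
    "pacific",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic population.

    Units: incomes in log-dollars (``income_lognormal_mu`` is the mean of
    log income), concentrations in ug/m3 (PM2.5) and ppb (O3), mortality in
    deaths per person-year.  ``exposure_income_slope`` and
    ``mortality_income_slope`` are standardized effects of the county-income
    z-score on (respectively) county concentration and log mortality; both
    are negative by default, encoding that poorer counties are both more
    polluted and sicker.
    """

    n_states: int = 20
    counties_per_state: int = 25
    households_per_county: int = 200
    income_lognormal_mu: float = 10.82  # exp -> ~$50k median
    income_lognormal_sigma: float = 0.87
    county_income_sd: float = 0.22  # SD of the county log-income component
    negative_income_rate: float = 4e-4
    exposure_income_slope: float = -0.55
    mortality_income_slope: float = -0.30
    mortality_noise_sd: float = 0.12
    cohort_base_rates: tuple[float, ...] = _DEFAULT_COHORT_RATES
    cohort_shares: tuple[float, ...] = _DEFAULT_COHORT_SHARES
    cohort_population: int = 100000  # persons per county x cohort cell
    pm25_mean: float = 10.2
    pm25_sd: float = 2.05
    o3_mean: float = 28.0
    o3_sd: float = 4.5
    monitor_noise_frac: float = 0.05  # monitor scatter as fraction of mean
    race_mixture: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RACE_MIXTURE)
    )
    race_income_shift: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RACE_SHIFT)
    )
    household_size_probs: tuple[float, ...] = _DEFAULT_HH_SIZE_PROBS
    year: int = 2011
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_states, self.counties_per_state, self.households_per_county) < 1:
            raise ValueError("counts must be positive")
        probs = np.array(list(self.race_mixture.values()))
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("race_mixture must be a probability distribution")
        rates = np.asarray(self.cohort_base_rates)
        if rates.size != N_COHORTS:
            raise ValueError(f"need {N_COHORTS} cohort base rates")
        if (rates <= 0).any() or (np.diff(rates) < 0).any():
            raise ValueError("cohort_base_rates must be positive and non-decreasing")
        if self.pm25_mean <= 0 or self.o3_mean <= 0:
            raise ValueError("pollutant means must be positive")
        shares = np.asarray(self.cohort_shares)
        if shares.size != N_COHORTS or (shares < 0).any():
            raise ValueError(f"need {N_COHORTS} non-negative cohort shares")

    def with_(self, **kwargs) -> "SynthConfig":
        """Copy with fields replaced (convenience for scenario grids)."""
        return replace(self, **kwargs)


def simulate_population(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (households, mortality, monitors) tables.

    Deterministic given ``config.seed``; two calls with the same config
    produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n_counties = config.n_states * config.counties_per_state
    n_hh = n_counties * config.households_per_county

    state_ids = np.array([f"S{i:02d}" for i in range(config.n_states)])
    county_state = np.repeat(np.arange(config.n_states), config.counties_per_state)
    county_ids = np.array(
        [
            f"S{s:02d}C{c:03d}"
            for s, c in zip(
                county_state, np.tile(np.arange(config.counties_per_state), config.n_states)
            )
        ]
    )
    division = np.array(
        [_DIVISIONS[s % len(_DIVISIONS)] for s in county_state]
    )

    # county-level log-income component
    county_effect = rng.normal(0.0, config.county_income_sd, size=n_counties)
    effect_sd = county_effect.std()
    if effect_sd > 0:
        county_z = (county_effect - county_effect.mean()) / effect_sd
    else:  # single county: no between-county gradient to encode
        county_z = np.zeros(n_counties)

    # households
    hh_county = np.repeat(np.arange(n_counties), config.households_per_county)
    races = rng.choice(
        list(config.race_mixture), size=n_hh, p=list(config.race_mixture.values())
    )
    race_shift = np.vectorize(config.race_income_shift.get)(races)
    log_income = (
        config.income_lognormal_mu
        + race_shift
        + county_effect[hh_county]
        + rng.normal(0.0, config.income_lognormal_sigma, size=n_hh)
    )
    income = np.exp(log_income)
    neg = rng.random(n_hh) < config.negative_income_rate
    income[neg] = -np.abs(rng.normal(0.0, 5000.0, size=int(neg.sum())))

    sizes = rng.choice(
        np.arange(1, len(config.household_size_probs) + 1),
        size=n_hh,
        p=np.asarray(config.household_size_probs)
        / np.sum(config.household_size_probs),
    )
    shares = np.asarray(config.cohort_shares, dtype=float)
    shares = shares / shares.sum()
    member_cohorts = rng.choice(
        np.arange(1, N_COHORTS + 1), size=int(sizes.sum()), p=shares
    )
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    cohort_strings = [
        "|".join(map(str, np.sort(member_cohorts[bounds[i] : bounds[i + 1]])))
        for i in range(n_hh)
    ]

    households = pd.DataFrame(
        {
            "household_id": [f"H{i:07d}" for i in range(n_hh)],
            "year": config.year,
            "state_id": state_ids[county_state][hh_county],
            "county_id": county_ids[hh_county],
            "market_income": np.round(income, 2),
            "member_age_cohorts": cohort_strings,
            "race": races,
            "census_division": division[hh_county],
        }
    )

    # county pollution, anti-correlated with county income
    slope = config.exposure_income_slope
    resid = np.sqrt(max(0.0, 1.0 - slope**2))
    pm25 = config.pm25_mean + config.pm25_sd * (
        slope * county_z + resid * rng.normal(size=n_counties)
    )
    o3 = config.o3_mean + config.o3_sd * (
        slope * county_z + resid * rng.normal(size=n_counties)
    )
    pm25 = np.maximum(pm25, 0.5)
    o3 = np.maximum(o3, 1.0)

    # monitors: 1-3 per county and pollutant, scattering around the county level
    monitor_rows = []
    for p, level, mean in (("PM25", pm25, config.pm25_mean), ("O3", o3, config.o3_mean)):
        counts = rng.integers(1, 4, size=n_counties)
        for c in range(n_counties):
            noise = rng.normal(0.0, config.monitor_noise_frac * mean, size=counts[c])
            for j, eps in enumerate(noise):
                monitor_rows.append(
                    (
                        f"{county_ids[c]}-{p}-{j}",
                        county_ids[c],
                        p,
                        max(round(level[c] + eps, 3), 0.0),
                    )
                )
    monitors = pd.DataFrame(
        monitor_rows, columns=["monitor_id", "county_id", "pollutant", "period_value"]
    )

    # mortality: cohort base rate x county income multiplier x noise
    base = np.asarray(config.cohort_base_rates)
    log_mult = config.mortality_income_slope * county_z[:, None] + rng.normal(
        0.0, config.mortality_noise_sd, size=(n_counties, N_COHORTS)
    )
    rates = np.clip(base[None, :] * np.exp(log_mult), 1e-6, 0.999)
    deaths = rng.poisson(rates * config.cohort_population)
    mortality = pd.DataFrame(
        {
            "county_id": np.repeat(county_ids, N_COHORTS),
            "age_cohort": np.tile(np.arange(1, N_COHORTS + 1), n_counties),
            "rate": rates.ravel(),
            "death_count": deaths.ravel(),
        }
    )

    logger.info(
        "simulate_population: %d households, %d counties, %d monitors",
        n_hh,
        n_counties,
        len(monitors),
    )
    return households, mortality, monitors


def write_tables(
    config: SynthConfig,
    out_dir,
) -> dict[str, str]:
    """Simulate and write the three tables as CSV; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    households, mortality, monitors = simulate_population(config)
    paths = {
        "households": str(out / "households.csv"),
        "mortality": str(out / "mortality.csv"),
        "monitors": str(out / "monitors.csv"),
    }
    households.to_csv(paths["households"], index=False)
    mortality.to_csv(paths["mortality"], index=False)
    monitors.to_csv(paths["monitors"], index=False)
    return paths


def load_config(path) -> SynthConfig:
    """Read a flat ``key = value`` config file into a SynthConfig.

    Unknown keys raise; dict-valued fields take ``key.subkey = value`` form.
    """
    fields = SynthConfig.__dataclass_fields__
    kwargs: dict = {}
    dicts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if "." in key:
                parent, sub = key.split(".", 1)
                if parent not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {parent!r}")
                dicts.setdefault(parent, {})[sub] = float(value)
                continue
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = fields[key].type
            if typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            elif "tuple" in str(typ):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            else:
                kwargs[key] = value
    kwargs.update(dicts)
    return SynthConfig(**kwargs)


def config_to_dict(config: SynthConfig) -> dict:
    """Flat dict of the config for run-metadata echoing."""
    return asdict(config)
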