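#!/usr/bin/env python
"""Compute household pollution damages and adjusted income.

Applies the attributable-risk model (M = gamma * (1 - e^(-beta*C)) per
member and pollutant), monetizes with the $10.2M VSL, sums to households,
and deducts from market income.  Writes the per-household damage table to
scratch/run/damages.csv and prints the headline magnitudes.
"""

import argparse
from pathlib import Path

import pandas as pd

from airineq import VSLSchedule, adjusted_income_table, household_damage
from airineq.damage import BELL_O3, KREWSKI_PM25

parser = argparse.ArgumentParser()
parser.add_argument("--prep-dir", type=Path, default=Path("scratch/run/prepared"))
parser.add_argument("--out", type=Path, default=Path("scratch/run/damages.csv"))
args = parser.parse_args()

hh = pd.read_csv(args.prep_dir / "households.csv", dtype={"state_id": str, "county_id": str})
mort = pd.read_csv(args.prep_dir / "mortality.csv", dtype={"county_id": str})
conc = pd.read_csv(args.prep_dir / "concentrations.csv", dtype={"county_id": str})

ledger = household_damage(
    hh, mort, conc, {"PM25": KREWSKI_PM25, "O3": BELL_O3}, VSLSchedule()
)
table = adjusted_income_table(ledger)
table.to_csv(args.out, index=False)

excl = ledger.attrs["exclusions"]
print(f"analysis sample: {len(table)} households "
      f"(excluded {excl['missing_mortality_cell']} with censored mortality cells, "
      f"{excl['unmonitored_county']} in unmonitored counties)")
print(f"mean market income : ${table['market_income'].mean():>12,.0f}")
print(f"mean damage        : ${table['damage'].mean():>12,.0f} "
      f"(PM2.5 ${table['damage_PM25'].mean():,.0f}, O3 ${table['damage_O3'].mean():,.0f})")
print(f"mean adjusted      : ${table['adjusted_income'].mean():>12,.0f}")
print(f"households with negative adjusted income: "
      f"{100 * table.attrs['share_negative_adjusted']:.1f}%")
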