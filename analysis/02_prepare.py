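#!/usr/bin/env python
"""Apply the three data-preparation rules to the raw tables.

Top-codes incomes at each state's 99.5th percentile (mean replacement above
the cut), drops mortality cells with fewer than 20 deaths, and averages
monitor readings to county-level concentrations.  Writes prepared tables
under scratch/run/prepared/ and reports how much each rule touched.
"""

import argparse
from pathlib import Path

from airineq import (
    aggregate_monitors,
    apply_topcoding,
    filter_reliable_mortality,
    read_households,
    read_monitors,
    read_mortality,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("scratch/run/data"))
parser.add_argument("--out-dir", type=Path, default=Path("scratch/run/prepared"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

hh = read_households(args.data_dir / "households.csv")
raw = hh["market_income"].to_numpy().copy()
hh["market_income"] = apply_topcoding(hh["market_income"], hh["state_id"])
n_topcoded = int((hh["market_income"].to_numpy() != raw).sum())

mort_raw = read_mortality(args.data_dir / "mortality.csv")
mort = filter_reliable_mortality(mort_raw)
conc = aggregate_monitors(read_monitors(args.data_dir / "monitors.csv"))

hh.to_csv(args.out_dir / "households.csv", index=False)
mort.to_csv(args.out_dir / "mortality.csv", index=False)
conc.to_csv(args.out_dir / "concentrations.csv", index=False)

print(f"top-coded {n_topcoded} of {len(hh)} household incomes")
print(f"mortality cells: {len(mort)} reliable of {len(mort_raw)} "
      f"({len(mort_raw) - len(mort)} censored at <20 deaths)")
print(f"county-pollutant concentrations: {len(conc)}")
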