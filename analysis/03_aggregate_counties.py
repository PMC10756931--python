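#!/usr/bin/env python
"""Stage 3 — population-weighted county fluoride estimates.

Aggregates system estimates to county weighted mean / P90 / P95 with
population-served weights, applies the 50% public-water coverage filter,
and reports the included / inadequate / no-data accounting.
"""

from pathlib import Path

import pandas as pd

from cwsfluoride import counties as cty

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    if not (OUT / "cws_estimates.csv").exists():
        raise SystemExit("run analysis/02_estimate_exposure.py first")
    est = pd.read_csv(OUT / "cws_estimates.csv")
    inventory = pd.read_csv(DATA / "inventory.csv")
    county_cov = pd.read_csv(DATA / "counties.csv")

    agg = cty.aggregate_counties(est, inventory, county_cov)
    agg.to_csv(OUT / "county_estimates.csv", index=False)

    counts = agg["status"].value_counts()
    print("county status accounting:")
    for status, n in counts.items():
        print(f"  {status}: {n}")
    inc = agg[agg["status"] == "included"]
    print(f"included counties: {len(inc)}")
    print(f"  weighted mean fluoride, median across counties: {inc['weighted_mean'].median():.0f} ug/L")
    print(f"  weighted P95, median across counties:           {inc['weighted_p95'].median():.0f} ug/L")
    print(f"wrote {OUT / 'county_estimates.csv'}")


if __name__ == "__main__":
    main()
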