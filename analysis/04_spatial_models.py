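#!/usr/bin/env python
"""Stage 4 — spatial diagnostics and spatial error models.

Builds queen-contiguity weights over the analysis counties, checks global
spatial autocorrelation (Moran's I, permutation test), runs LM diagnostics
for lag-vs-error dependence, then fits maximum-likelihood spatial error
models of log county fluoride on racial/ethnic composition (percent/10)
adjusted for groundwater reliance, population density and social
vulnerability (Model 1), plus county fluoridation coverage (Model 2).
Writes the GMR table to ``results/table3.csv``.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cwsfluoride import spatial

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    if not (OUT / "county_estimates.csv").exists():
        raise SystemExit("run analysis/03_aggregate_counties.py first")
    est = pd.read_csv(OUT / "county_estimates.csv")
    cov = pd.read_csv(DATA / "counties.csv")
    adj = pd.read_csv(DATA / "adjacency.csv")

    merged = est.merge(cov, on="county_id")
    analysis = merged[(merged["status"] == "included") & (merged["weighted_mean"] > 0)]
    full_w = spatial.build_queen_weights(
        list(adj.itertuples(index=False, name=None)), cov["county_id"].tolist()
    )
    sw = full_w.subset(analysis["county_id"].tolist())
    while sw.islands:
        analysis = analysis[~analysis["county_id"].isin(sw.islands)]
        sw = full_w.subset(analysis["county_id"].tolist())

    moran = spatial.morans_i(analysis["weighted_mean"].to_numpy(), sw, 999, seed=1)
    print(f"Moran's I on county weighted-mean fluoride: {moran.i:.3f} "
          f"(perm p = {moran.p_perm:.3f}, null expectation {moran.expected:.4f})")

    x, _ = spatial._model_design(analysis, "pct_hispanic", 10.0, 1)
    lm = spatial.lm_diagnostics(np.log(analysis["weighted_mean"].to_numpy()), x, sw)
    print(f"LM-error = {lm.lm_error:.1f} (p = {lm.p_error:.2e}); "
          f"LM-lag = {lm.lm_lag:.1f} (p = {lm.p_lag:.2e})")

    table3, _ = spatial.run_models(analysis, sw)
    table3.to_csv(OUT / "table3.csv", index=False)
    for _, r in table3.iterrows():
        print(
            f"  {r['group']:>9s} model {r['model']}: n={r['n']}, "
            f"GMR {r['gmr']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f}), "
            f"{r['pct_change']:+d}% change, lambda={r['lambda']:.2f}"
        )
    diag = {
        "moran_i": moran.i, "moran_p_perm": moran.p_perm,
        "lm_error": lm.lm_error, "p_error": lm.p_error,
        "lm_lag": lm.lm_lag, "p_lag": lm.p_lag,
        "n_counties": int(len(analysis)),
    }
    (OUT / "diagnostics.json").write_text(json.dumps(diag, indent=2, sort_keys=True))
    print(f"wrote {OUT / 'table3.csv'} and {OUT / 'diagnostics.json'}")


if __name__ == "__main__":
    main()
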