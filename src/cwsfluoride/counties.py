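"""Population-weighted county aggregation of CWS fluoride estimates.

A county's exposure summary is built from the systems serving it, each
weighted by the population it serves divided by the total served in the
county.  Counties whose monitored systems cover less than 50% of the
public-water-reliant population are flagged ``inadequate``; counties with no
monitored systems at all are ``no_data``.  Regression analysis sets are
further restricted to counties with at least a minimum number of residents
(default 100) of the racial/ethnic group under study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_population_weights",
    "weighted_mean",
    "weighted_quantile",
    "apply_coverage_filter",
    "percent_fluoridated",
    "restrict_by_group_count",
    "aggregate_counties",
]


def compute_population_weights(populations) -> np.ndarray:
    """Per-system weights: population served / county total served."""
    pops = np.asarray(populations, dtype=float)
    if len(pops) == 0:
        raise ValueError("no systems serving county")
    total = pops.sum()
    if total <= 0:
        raise ValueError("zero total population served; county must be excluded")
    return pops / total


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    return float(values @ weights)


def weighted_quantile(values, weights, q: float, method: str = "cumulative") -> float:
    """Weighted quantile of system estimates.

    ``cumulative`` (default): smallest value whose cumulative weight, with
    values sorted ascending, reaches q — deterministic and consistent with
    replicating each system in proportion to its weight.  ``interpolate``
    linearly interpolates between weight midpoints.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(values) == 0:
        raise ValueError("empty input")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    if method == "cumulative":
        idx = int(np.searchsorted(cum, q - 1e-12))
        return float(v[min(idx, len(v) - 1)])
    if method == "interpolate":
        mid = cum - 0.5 * w
        return float(np.interp(q, mid, v))
    raise ValueError(f"unknown method {method!r}")


def apply_coverage_filter(population_served_total: float, public_water_population) -> bool | None:
    """Included iff served/total >= 0.5; None when the denominator is missing."""
    if public_water_population is None or not np.isfinite(public_water_population):
        return None
    if public_water_population <= 0:
        raise ValueError("public-water-reliant population must be positive")
    return population_served_total / public_water_population >= 0.5


def percent_fluoridated(flags, weights) -> float:
    """Population-weighted percent served by systems reporting fluoridation.

    Missing flags count as not fluoridated (voluntary reporting is
    incomplete); callers track how many were missing.
    """
    f = pd.Series(flags).fillna(0.0).astype(float).to_numpy() > 0
    return float(100.0 * np.asarray(weights, dtype=float)[f].sum())


def restrict_by_group_count(
    counties: pd.DataFrame, count_col: str, min_count: int = 100
) -> pd.DataFrame:
    """Counties with at least ``min_count`` residents of the group."""
    if count_col not in counties.columns:
        raise ValueError(f"unknown group count column {count_col!r}")
    return counties[counties[count_col] >= min_count]


def aggregate_counties(
    estimates: pd.DataFrame,
    inventory: pd.DataFrame,
    counties: pd.DataFrame,
    quantile_method: str = "cumulative",
) -> pd.DataFrame:
    """Population-weighted county estimates with coverage status.

    One inventory row per (system, county served); a multi-county system
    contributes its full population served to each county's weights.
    Returns one row per county: weighted_mean, weighted_p90, weighted_p95,
    n_systems, coverage_fraction, pct_fluoridated and
    status in {included, inadequate, no_data}.
    """
    merged = inventory.merge(estimates, on="system_id", how="inner")
    rows = []
    for cid, cty in counties.set_index("county_id").iterrows():
        g = merged[merged["county_id"] == cid]
        denom = cty.get("public_water_population", np.nan)
        if len(g) == 0:
            rows.append(
                {
                    "county_id": cid,
                    "weighted_mean": np.nan,
                    "weighted_p90": np.nan,
                    "weighted_p95": np.nan,
                    "n_systems": 0,
                    "coverage_fraction": 0.0 if np.isfinite(denom) else np.nan,
                    "pct_fluoridated": np.nan,
                    "status": "no_data",
                }
            )
            continue
        w = compute_population_weights(g["population_served"])
        x = g["mean_6yr"].to_numpy()
        served = float(g["population_served"].sum())
        included = apply_coverage_filter(served, float(denom) if np.isfinite(denom) else None)
        if included is None:
            status, covfrac = "no_data", np.nan
        else:
            status = "included" if included else "inadequate"
            covfrac = served / float(denom)
        rows.append(
            {
                "county_id": cid,
                "weighted_mean": weighted_mean(x, w),
                "weighted_p90": weighted_quantile(x, w, 0.90, quantile_method),
                "weighted_p95": weighted_quantile(x, w, 0.95, quantile_method),
                "n_systems": len(g),
                "coverage_fraction": covfrac,
                "pct_fluoridated": percent_fluoridated(g["fluoridation_reported"], w),
                "status": status,
            }
        )
    return pd.DataFrame(rows)
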