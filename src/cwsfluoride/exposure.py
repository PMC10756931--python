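"""CWS-level fluoride concentration estimates and subgroup summaries.

Turns raw compliance monitoring records into six-year average fluoride
concentrations per community water system (CWS):

1. standardize units to µg/L (mg/L values multiplied by 1000);
2. substitute left-censored nondetects by the record-specific limit of
   detection divided by sqrt(2);
3. average within each system-calendar-year, using treated samples only
   whenever the untreated (raw) yearly average exceeds the treated one —
   distributed water is what consumers drink;
4. average the yearly means over the analysis window (2006-2011 default)
   to obtain a chronic concentration estimate per system.

Subgroup summaries mirror a stratified exceedance table: counts and percents
of systems above guidance thresholds (700 / 1500 / 4000 µg/L by default),
means with normal-approximation 95% CIs, empirical 90th/95th percentiles,
total population served, and Kruskal-Wallis tests across strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_THRESHOLDS",
    "standardize_units",
    "substitute_nondetects",
    "yearly_average",
    "yearly_averages",
    "chronic_average",
    "cws_estimates",
    "count_exceedances",
    "summarize_subgroups",
    "kruskal_wallis",
    "percent_of_total",
    "QCLog",
]

DEFAULT_THRESHOLDS = (700.0, 1500.0, 4000.0)

_UNIT_FACTORS = {
    "ug/l": 1.0,
    "µg/l": 1.0,
    "ug/L": 1.0,
    "mg/l": 1000.0,
}


@dataclass
class QCLog:
    """Counts of records/systems dropped along the way; part of the results."""

    n_records_in: int = 0
    n_outside_window: int = 0
    n_negative_detected: int = 0
    n_bad_nondetect_lod: int = 0
    n_records_used: int = 0
    n_systems: int = 0
    notes: list = field(default_factory=list)

    def lines(self) -> list[str]:
        out = [
            f"records read: {self.n_records_in}",
            f"records outside window dropped: {self.n_outside_window}",
            f"detected records with negative value dropped: {self.n_negative_detected}",
            f"nondetect records with missing/non-positive LOD dropped: {self.n_bad_nondetect_lod}",
            f"records used: {self.n_records_used}",
            f"systems with estimates: {self.n_systems}",
        ]
        return out + list(self.notes)


def standardize_units(records: pd.DataFrame) -> pd.DataFrame:
    """Convert ``value`` and ``lod`` to µg/L in place of mixed units."""
    units = records["units"].astype(str).str.strip().str.lower()
    factor = units.map({k.lower(): v for k, v in _UNIT_FACTORS.items()})
    if factor.isna().any():
        bad = records.loc[factor.isna()].iloc[0]
        raise ValueError(
            f"unrecognized units {bad['units']!r} on record for system {bad['system_id']!r}"
        )
    out = records.copy()
    out["value"] = records["value"] * factor
    out["lod"] = records["lod"] * factor
    out["units"] = "ug/L"
    return out


def substitute_nondetects(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Impute nondetects at LOD/sqrt(2); reject nondetects with unusable LOD.

    Returns the imputed table and the count of rejected nondetect records
    (missing or non-positive LOD), which callers log.
    """
    out = records.copy()
    nd = ~out["detected"].astype(bool)
    bad = nd & (~np.isfinite(out["lod"]) | (out["lod"] <= 0))
    n_bad = int(bad.sum())
    out = out[~bad].copy()
    nd = ~out["detected"].astype(bool)
    out.loc[nd, "value"] = out.loc[nd, "lod"] / math.sqrt(2.0)
    return out, n_bad


def yearly_average(records: pd.DataFrame) -> tuple[float, bool]:
    """Average one system-year of records, reconciling treated vs raw.

    Default is the arithmetic mean of all records in the year.  When both
    treated and raw samples exist and the raw mean exceeds the treated mean,
    only treated samples are averaged (flag True).  A year with only raw
    samples uses the raw mean (no treated comparator exists).
    """
    if len(records) == 0:
        raise ValueError("no records in system-year")
    treated = records.loc[records["sample_type"] == "treated", "value"]
    raw = records.loc[records["sample_type"] == "raw", "value"]
    if len(treated) and len(raw) and raw.mean() > treated.mean():
        return float(treated.mean()), True
    return float(records["value"].mean()), False


def yearly_averages(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-(system, year) means with the treated/raw override.

    Returns columns system_id, year, yearly_mean, treated_only.
    """
    df = records.copy()
    df["year"] = pd.to_datetime(df["sample_date"]).dt.year
    grp = df.groupby(["system_id", "year"], sort=True)
    mean_all = grp["value"].mean()
    by_type = df.pivot_table(
        index=["system_id", "year"], columns="sample_type", values="value", aggfunc="mean"
    )
    t = by_type.get("treated")
    r = by_type.get("raw")
    if t is None:
        t = pd.Series(np.nan, index=by_type.index)
    if r is None:
        r = pd.Series(np.nan, index=by_type.index)
    override = t.notna() & r.notna() & (r > t)
    yearly = mean_all.where(~override, t)
    out = yearly.rename("yearly_mean").reset_index()
    out["treated_only"] = override.reindex(out.set_index(["system_id", "year"]).index).to_numpy()
    return out


def chronic_average(yearly: pd.DataFrame, window: tuple[int, int] = (2006, 2011)) -> pd.DataFrame:
    """Unweighted mean of yearly means inside the window, per system.

    Systems with no yearly mean inside the window are omitted (callers log
    the count).  Returns system_id, mean_6yr, n_years, any_raw_override.
    """
    lo, hi = window
    inside = yearly[(yearly["year"] >= lo) & (yearly["year"] <= hi)]
    if len(inside) == 0:
        return pd.DataFrame(columns=["system_id", "mean_6yr", "n_years", "any_raw_override"])
    agg = inside.groupby("system_id", sort=True).agg(
        mean_6yr=("yearly_mean", "mean"),
        n_years=("yearly_mean", "size"),
        any_raw_override=("treated_only", "any"),
    )
    return agg.reset_index()


def cws_estimates(
    records: pd.DataFrame, window: tuple[int, int] = (2006, 2011)
) -> tuple[pd.DataFrame, QCLog]:
    """Full record-to-system pipeline: QC, units, substitution, averaging."""
    qc = QCLog(n_records_in=len(records))
    df = standardize_units(records)
    year = pd.to_datetime(df["sample_date"]).dt.year
    in_window = (year >= window[0]) & (year <= window[1])
    qc.n_outside_window = int((~in_window).sum())
    df = df[in_window]
    neg = df["detected"].astype(bool) & (df["value"] < 0)
    qc.n_negative_detected = int(neg.sum())
    df = df[~neg]
    df, qc.n_bad_nondetect_lod = substitute_nondetects(df)
    qc.n_records_used = len(df)

    yearly = yearly_averages(df)
    est = chronic_average(yearly, window)
    counts = df.groupby("system_id").agg(
        n_records=("value", "size"),
        n_nondetect=("detected", lambda d: int((~d.astype(bool)).sum())),
    )
    est = est.merge(counts, on="system_id", how="left")
    qc.n_systems = len(est)
    return est, qc


def count_exceedances(
    estimates: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    populations: pd.Series | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Systems above each threshold: count, percent (one decimal), population.

    ``strict`` counts systems with mean_6yr strictly above the threshold
    (set False for >=).  ``populations`` is an optional per-row population
    served aligned with ``estimates``.
    """
    x = estimates["mean_6yr"].to_numpy()
    n = len(x)
    rows = []
    for thr in thresholds:
        mask = x > thr if strict else x >= thr
        cnt = int(mask.sum())
        row = {
            "threshold_ug_l": thr,
            "n_exceed": cnt,
            "pct_exceed": percent_of_total(cnt, n) if n else float("nan"),
        }
        if populations is not None:
            row["population_exceed"] = int(np.asarray(populations)[mask].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _group_frame(estimates: pd.DataFrame, systems: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Join estimates to system metadata, de-duplicated for the grouping.

    The inventory has one row per (system, county served).  For the
    sociodemographic-cluster analysis a multi-county system appears once per
    distinct cluster it serves; for every other grouping each system appears
    exactly once.
    """
    merged = estimates.merge(systems, on="system_id", how="inner")
    if grouping == "cluster":
        return merged.drop_duplicates(["system_id", "cluster"])
    return merged.drop_duplicates("system_id")


def summarize_subgroups(
    estimates: pd.DataFrame,
    systems: pd.DataFrame,
    grouping: str,
    thresholds=DEFAULT_THRESHOLDS,
    strict: bool = True,
) -> pd.DataFrame:
    """Stratified exceedance/summary table for one grouping variable.

    Per stratum: n systems, exceedance counts and percents per threshold,
    mean with normal-approximation 95% CI, empirical 90th and 95th
    percentiles (linear interpolation), and total population served.
    """
    df = _group_frame(estimates, systems, grouping)
    if grouping == "fluoridation":
        df = df[df["fluoridation_reported"].notna()].copy()
        df["fluoridation"] = np.where(
            df["fluoridation_reported"].astype(float) > 0, "fluoridated", "not fluoridated"
        )
    rows = []
    for label, g in df.groupby(grouping, sort=True, observed=True):
        x = g["mean_6yr"].to_numpy()
        n = len(x)
        row = {"group": str(label), "n_systems": n}
        if n == 0:
            rows.append(row)
            continue
        for thr in thresholds:
            mask = x > thr if strict else x >= thr
            cnt = int(mask.sum())
            row[f"n_exceed_{int(thr)}"] = cnt
            row[f"pct_exceed_{int(thr)}"] = percent_of_total(cnt, n)
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        half = 1.959963984540054 * sd / math.sqrt(n)
        row.update(
            mean=float(np.mean(x)),
            ci_low=float(np.mean(x) - half),
            ci_high=float(np.mean(x) + half),
            p90=float(np.percentile(x, 90)),
            p95=float(np.percentile(x, 95)),
            population_total=int(g["population_served"].sum()),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with ties correction, chi-square p-value.

    All-identical observations return (0, 1) by convention rather than an
    undefined ties correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def percent_of_total(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total, rounded half-even to the requested precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_EVEN)
    )
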