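"""End-to-end orchestration: records -> CWS -> county -> spatial models.

One configuration drives every stage; one seed governs all randomness
(synthesis and permutation inference).  Outputs mirror the analysis's
reporting surface: a stratified exceedance table (``table1.csv``), analysis-
set descriptives (``table2.csv``), GMRs per racial/ethnic group and model
(``table3.csv``), spatial diagnostics (``diagnostics.json``) and a QC log
whose N-accounting (dropped records, excluded counties, islands) is a
first-class result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counties as county_mod
from . import exposure, spatial
from .synthetic import SyntheticConfig, simulate

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "describe_analysis_sets"]

GROUPINGS = ["source_type", "size_category", "region", "cluster", "correctional", "fluoridation"]


@dataclass
class RunConfig:
    """Flat configuration for a full run (YAML-loadable)."""

    simulate: bool = True
    simulate_overrides: dict = field(default_factory=dict)
    records_csv: str | None = None
    inventory_csv: str | None = None
    counties_csv: str | None = None
    adjacency_csv: str | None = None
    window: tuple = (2006, 2011)
    thresholds: tuple = exposure.DEFAULT_THRESHOLDS
    outcome: str = "weighted_mean"         # or weighted_p95
    composition_scale: float = 10.0        # 60 for the majority-community sensitivity
    models: tuple = (1, 2)
    min_group_count: int = 100
    n_permutations: int = 999
    moran_on_log: bool = False
    strict_exceedance: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        thr = tuple(float(t) for t in self.thresholds)
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = thr
        self.window = tuple(int(y) for y in self.window)
        if self.window[0] > self.window[1]:
            raise ValueError("window start must not exceed end")
        if float(self.composition_scale) not in (10.0, 60.0):
            raise ValueError("composition scale must be 10 or 60")
        if self.outcome not in ("weighted_mean", "weighted_p95"):
            raise ValueError("outcome must be weighted_mean or weighted_p95")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    estimates: pd.DataFrame
    county_estimates: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    diagnostics: dict
    qc_lines: list
    fits: dict


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        overrides = dict(cfg.simulate_overrides)
        overrides.setdefault("seed", cfg.seed)
        overrides.setdefault("years", cfg.window)
        data = simulate(SyntheticConfig(**overrides))
        return data["records"], data["inventory"], data["counties"], data["adjacency"]
    frames = []
    for name, path in (
        ("records", cfg.records_csv),
        ("inventory", cfg.inventory_csv),
        ("counties", cfg.counties_csv),
        ("adjacency", cfg.adjacency_csv),
    ):
        if path is None:
            raise ValueError(f"{name} CSV path required when simulate is false")
        frames.append(pd.read_csv(path))
    return tuple(frames)


def describe_analysis_sets(
    merged: pd.DataFrame,
    min_count: int = 100,
    groups=None,
) -> pd.DataFrame:
    """Mean (SD) descriptives for all analysis counties and per-group subsets."""
    groups = dict(groups) if groups is not None else spatial.COMPOSITION_GROUPS
    stat_cols = [
        "weighted_mean", "population", "density", "pct_groundwater", "svi",
        "pct_fluoridated", "pct_hispanic", "pct_nh_black", "pct_aian", "pct_nh_white",
    ]
    rows = []
    subsets = {"all": merged}
    for gname, (_, count_col) in groups.items():
        subsets[gname] = county_mod.restrict_by_group_count(merged, count_col, min_count)
    for name, sub in subsets.items():
        row = {"analysis_set": name, "n_counties": len(sub)}
        for col in stat_cols:
            if col in sub.columns and len(sub):
                row[f"{col}_mean"] = float(sub[col].mean())
                row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    records, inventory, counties, adjacency = _load_inputs(cfg)
    qc: list[str] = []

    estimates, qclog = exposure.cws_estimates(records, cfg.window)
    qc.extend(qclog.lines())

    # stratified subgroup summaries with Kruskal-Wallis p-values
    t1_parts = []
    merged_sys = exposure._group_frame(estimates, inventory, "source_type")
    for grouping in GROUPINGS:
        summ = exposure.summarize_subgroups(
            estimates, inventory, grouping, cfg.thresholds, cfg.strict_exceedance
        )
        summ.insert(0, "grouping", grouping)
        frame = exposure._group_frame(estimates, inventory, grouping)
        if grouping == "fluoridation":
            frame = frame[frame["fluoridation_reported"].notna()].copy()
            frame["fluoridation"] = np.where(
                frame["fluoridation_reported"].astype(float) > 0,
                "fluoridated", "not fluoridated",
            )
        labels = frame[grouping].astype(str)
        try:
            _, p = exposure.kruskal_wallis(frame["mean_6yr"].to_numpy(), labels.to_numpy())
        except ValueError:
            p = np.nan
        summ["kruskal_p"] = p
        t1_parts.append(summ)
    table1 = pd.concat(t1_parts, ignore_index=True)

    # County aggregation and status accounting
    county_est = county_mod.aggregate_counties(estimates, inventory, counties)
    status_counts = county_est["status"].value_counts().to_dict()
    qc.append(f"county status counts: {json.dumps(status_counts, sort_keys=True)}")
    merged = county_est.merge(counties, on="county_id", how="left")
    analysis = merged[merged["status"] == "included"].copy()
    analysis = analysis[np.isfinite(analysis[cfg.outcome]) & (analysis[cfg.outcome] > 0)]
    if len(analysis) == 0:
        raise ValueError("no counties remain after the coverage filter")

    # Spatial weights restricted to analysis counties; islands dropped
    full_w = spatial.build_queen_weights(
        list(adjacency.itertuples(index=False, name=None)), counties["county_id"].tolist()
    )
    sw = full_w.subset(analysis["county_id"].tolist())
    n_islands = 0
    while sw.islands:
        n_islands += len(sw.islands)
        analysis = analysis[~analysis["county_id"].isin(sw.islands)]
        sw = full_w.subset(analysis["county_id"].tolist())
    qc.append(f"islands excluded from spatial analyses: {n_islands}")

    moran_vals = analysis[cfg.outcome].to_numpy()
    if cfg.moran_on_log:
        moran_vals = np.log(moran_vals)
    moran = spatial.morans_i(moran_vals, sw, cfg.n_permutations, seed=cfg.seed)

    diagnostics = {
        "moran_i": moran.i,
        "moran_expected": moran.expected,
        "moran_p_norm": moran.p_norm,
        "moran_p_perm": moran.p_perm,
        "n_analysis_counties": int(len(analysis)),
        "lm": {},
    }
    table3, fits = spatial.run_models(
        analysis,
        sw,
        outcome=cfg.outcome,
        scale=cfg.composition_scale,
        models=cfg.models,
        min_count=cfg.min_group_count,
    )
    for gname, (comp_col, count_col) in spatial.COMPOSITION_GROUPS.items():
        sub = analysis[analysis[count_col] >= cfg.min_group_count]
        sub_w = sw.subset(sub["county_id"].tolist())
        while sub_w.islands:
            sub = sub[~sub["county_id"].isin(sub_w.islands)]
            sub_w = sw.subset(sub["county_id"].tolist())
        if len(sub) < 10:
            continue
        x, _ = spatial._model_design(sub, comp_col, cfg.composition_scale, 1)
        lm = spatial.lm_diagnostics(np.log(sub[cfg.outcome].to_numpy()), x, sub_w)
        diagnostics["lm"][gname] = {
            "lm_error": lm.lm_error, "p_error": lm.p_error,
            "lm_lag": lm.lm_lag, "p_lag": lm.p_lag,
        }

    table2 = describe_analysis_sets(analysis, cfg.min_group_count)
    qc.append(f"systems in subgroup analyses: {len(merged_sys)}")

    result = PipelineResult(
        estimates=estimates,
        county_estimates=county_est,
        table1=table1,
        table2=table2,
        table3=table3,
        diagnostics=diagnostics,
        qc_lines=qc,
        fits=fits,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(out / "cws_estimates.csv", index=False)
        county_est.to_csv(out / "county_estimates.csv", index=False)
        table1.to_csv(out / "table1.csv", index=False)
        table2.to_csv(out / "table2.csv", index=False)
        table3.to_csv(out / "table3.csv", index=False)
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
        (out / "qc_log.txt").write_text("\n".join(qc) + "\n")
    return result
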