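"""Synthetic compliance-monitoring, inventory, county and adjacency data.

Emulates the statistical structure of the real inputs to the fluoride
exposure analysis — routine compliance monitoring records, a water-system
inventory, county sociodemographic covariates, and county contiguity —
without any real data.  Counties sit on a rectangular grid with queen
(8-neighbour) adjacency standing in for real county topology.

The generative model is the one the downstream analysis assumes:

* county latent log fluoride  m_c = b0 + X_c beta + region effect + u_c,
  with spatially autocorrelated errors u = lambda W u + eps,
  eps ~ N(0, sigma_spatial^2), realized by solving (I - lambda W) u = eps
  with the row-standardized queen weights W;
* system log concentration   m_s = m_c + N(0, sigma_cws^2), optionally
  lifted toward a fluoridation set-point on the concentration scale for
  systems that report manual fluoridation;
* record log concentration   m_s + N(0, sigma_record^2), censored below a
  record-specific limit of detection (nondetects have their value blanked),
  reported in a mix of mg/L and µg/L, and flagged raw (untreated) for a
  configured fraction with a multiplicative raw bias.

A truth record (planted coefficients, spatial parameter, county latent
means) is returned for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial import build_queen_weights

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_grid_adjacency",
    "generate_county_covariates",
    "generate_system_inventory",
    "generate_monitoring_records",
    "simulate",
    "REGIONS",
    "CLUSTERS",
]

REGIONS = [
    "Alaska/Hawaii",
    "Central Midwest",
    "Eastern Midwest",
    "Mid-Atlantic",
    "New England",
    "Pacific Northwest",
    "Southeast",
    "Southwest",
]

CLUSTERS = [
    "Semi-Urban, High SES",
    "Semi-Urban, Mid/Low SES",
    "Semi-Urban, Hispanic",
    "Mostly Rural, Mid-SES",
    "Rural, Mid/Low SES",
    "Young, Urban, Mid/High SES",
    "Rural, American Indian",
    "Rural, High SES",
]

# baseline cluster frequencies (roughly the share of systems per cluster in
# national inventories); the Hispanic cluster weight scales with county
# Hispanic/Latino percent
_CLUSTER_BASE = np.array([0.38, 0.04, 0.10, 0.24, 0.015, 0.03, 0.015, 0.14])

# mean composition targets (Hispanic/Latino, non-Hispanic Black, AIAN,
# non-Hispanic White, other) as Dirichlet concentrations
_DIRICHLET_ALPHA = np.array([1.0, 0.7, 0.2, 7.9, 0.2])

EPA_SIZE_BINS = [0, 500, 3300, 10_000, np.inf]
EPA_SIZE_LABELS = ["<=500", "501-3300", "3301-10000", ">10000"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic pipeline.

    Scales are log-µg/L; composition coefficients in ``beta`` apply to the
    covariate scaled as percent/10 (one unit = 10 percentage points).
    """

    n_county_rows: int = 20
    n_county_cols: int = 20
    systems_per_county_mean: float = 3.0      # 1 + Poisson(mean - 1)
    pop_min: float = 100.0                    # log-uniform population served
    pop_max: float = 100_000.0
    frac_groundwater_systems: float = 0.9
    # planted composition effects per 10 percentage points (log scale)
    beta: dict = field(
        default_factory=lambda: {
            "pct_hispanic": float(np.log(1.15)),
            "pct_nh_black": 0.0,
            "pct_aian": 0.0,
            "pct_nh_white": 0.0,
        }
    )
    intercept: float = float(np.log(250.0))   # log-µg/L baseline
    beta_groundwater: float = 0.5             # per 100% county groundwater reliance
    beta_svi: float = 0.0
    region_effects: dict = field(
        default_factory=lambda: {
            "Southwest": 0.25,
            "Eastern Midwest": 0.15,
            "Mid-Atlantic": -0.35,
            "Alaska/Hawaii": -0.6,
        }
    )
    lambda_true: float = 0.5
    sigma_spatial: float = 0.5
    sigma_cws: float = 0.3
    sigma_record: float = 0.2
    lod_ug_l: float = 310.0                   # default gives ~30% nondetects
    frac_raw_samples: float = 0.2
    raw_bias: float = 1.1                     # multiplicative, >= 1
    frac_mg_l: float = 0.5                    # records reported in mg/L
    frac_fluoridated: float = 0.24            # among systems with a CDC report
    frac_fluoridation_missing: float = 0.21
    fluoridation_setpoint: float = 700.0      # µg/L
    fluoridation_strength: float = 0.6        # 0 disables the boost
    frac_tribal: float = 0.02
    frac_correctional: float = 0.006
    extra_records_mean: float = 4.0           # extra records beyond the schedule
    coverage_lo: float = 0.4                  # served/public-water-reliant ratio
    coverage_hi: float = 1.1
    multi_county_frac: float = 0.0
    years: tuple = (2006, 2011)
    seed: int = 0

    def validate(self) -> None:
        if self.n_county_rows < 2 or self.n_county_cols < 2:
            raise ValueError("county grid must be at least 2x2")
        for name in ("sigma_spatial", "sigma_cws", "sigma_record"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 < self.lambda_true < 1:
            raise ValueError("lambda_true must lie in (-1, 1)")
        if not 0 <= self.frac_groundwater_systems <= 1:
            raise ValueError("frac_groundwater_systems must be in [0, 1]")
        if self.raw_bias < 1:
            raise ValueError("raw_bias must be >= 1")
        if self.years[0] > self.years[1]:
            raise ValueError("years range is inverted")

    @classmethod
    def recovery(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Conditions for parameter-recovery experiments.

        The planted composition effect is only identifiable end-to-end when
        no other mechanism bends the county log-mean: the fluoridation boost
        and region offsets are disabled, between-system noise is kept small
        relative to the spatial signal, and the LOD sits low enough that
        censoring substitution does not flatten the lower tail.  Coverage is
        kept at or above 50% everywhere because randomly deleting counties
        thins the contiguity lattice and misattributes correlation carried
        by the missing neighbors, attenuating the spatial parameter.  All
        other machinery (censoring, raw/treated reconciliation, mixed units,
        population weighting) stays active.
        """
        base = dict(
            seed=seed,
            fluoridation_strength=0.0,
            region_effects={},
            sigma_cws=0.1,
            sigma_record=0.1,
            lod_ug_l=100.0,
            coverage_lo=0.55,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    beta_true: dict
    lambda_true: float
    gmr_true_per_10pct: dict
    county_latent_log_mean: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def generate_grid_adjacency(n_rows: int, n_cols: int) -> list[tuple[str, str]]:
    """Queen (8-neighbour) adjacency for an ``n_rows x n_cols`` county grid.

    Two cells are neighbors iff their row and column indices each differ by
    at most one (and they are distinct) — the grid analogue of queen
    contiguity, where sharing a corner suffices.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    edges.append((_county_id(r, c, n_cols), _county_id(rr, cc, n_cols)))
    return edges


def _county_id(r: int, c: int, n_cols: int) -> str:
    return f"C{r * n_cols + c:04d}"


def generate_county_covariates(
    config: SyntheticConfig, edges: list[tuple[str, str]]
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """County covariate table plus the latent log-mean truth record.

    Racial/ethnic percents come from a Dirichlet over (Hispanic/Latino,
    non-Hispanic Black, AIAN, non-Hispanic White, other), so they sum to
    at most 100.  The county latent log fluoride is X beta + region effect
    + u with u = lambda W u + eps solved against the row-standardized queen
    weights.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    nr, nc = config.n_county_rows, config.n_county_cols
    n = nr * nc
    ids = [_county_id(r, c, nc) for r in range(nr) for c in range(nc)]
    rows = np.repeat(np.arange(nr), nc)
    cols = np.tile(np.arange(nc), nr)

    comp = rng.dirichlet(_DIRICHLET_ALPHA, size=n) * 100.0
    pct_hispanic, pct_nh_black, pct_aian, pct_nh_white = comp[:, :4].T
    population = np.round(rng.lognormal(np.log(25_000.0), 1.2, size=n)).astype(int) + 50
    density = rng.lognormal(np.log(60.0), 1.3, size=n)
    svi = rng.beta(2.0, 2.0, size=n)
    pct_groundwater = 100.0 * rng.beta(2.0 * 0.67, 2.0 * 0.33, size=n)

    # regions as vertical bands of the grid; clusters sampled with the
    # Hispanic cluster upweighted by county Hispanic percent
    region_idx = np.minimum((cols * len(REGIONS)) // nc, len(REGIONS) - 1)
    region = np.array(REGIONS)[region_idx]
    cluster = np.empty(n, dtype=object)
    hisp_pos = CLUSTERS.index("Semi-Urban, Hispanic")
    for i in range(n):
        wts = _CLUSTER_BASE.copy()
        wts[hisp_pos] *= 1.0 + pct_hispanic[i] / 10.0
        cluster[i] = rng.choice(CLUSTERS, p=wts / wts.sum())

    sw = build_queen_weights(edges, ids)
    eig = sw.eigenvalues()
    if not (1.0 / eig.min() < config.lambda_true < 1.0 / eig.max()):
        raise ValueError("lambda_true outside the invertibility range of (I - lambda W)")
    eps = rng.normal(0.0, config.sigma_spatial, size=n)
    u = np.linalg.solve(np.eye(n) - config.lambda_true * sw.w, eps)

    latent = (
        config.intercept
        + config.beta.get("pct_hispanic", 0.0) * pct_hispanic / 10.0
        + config.beta.get("pct_nh_black", 0.0) * pct_nh_black / 10.0
        + config.beta.get("pct_aian", 0.0) * pct_aian / 10.0
        + config.beta.get("pct_nh_white", 0.0) * pct_nh_white / 10.0
        + config.beta_groundwater * pct_groundwater / 100.0
        + config.beta_svi * svi
        + np.array([config.region_effects.get(r, 0.0) for r in region])
        + u
    )

    df = pd.DataFrame(
        {
            "county_id": ids,
            "grid_row": rows,
            "grid_col": cols,
            "region": region,
            "cluster": cluster,
            "population": population,
            "density": density,
            "svi": svi,
            "pct_groundwater": pct_groundwater,
            "pct_hispanic": pct_hispanic,
            "pct_nh_black": pct_nh_black,
            "pct_aian": pct_aian,
            "pct_nh_white": pct_nh_white,
            "n_hispanic": np.round(population * pct_hispanic / 100.0).astype(int),
            "n_nh_black": np.round(population * pct_nh_black / 100.0).astype(int),
            "n_aian": np.round(population * pct_aian / 100.0).astype(int),
            "n_nh_white": np.round(population * pct_nh_white / 100.0).astype(int),
            "latent_log_mean": latent,
        }
    )
    truth = SyntheticTruth(
        beta_true=dict(config.beta),
        lambda_true=config.lambda_true,
        gmr_true_per_10pct={k: float(np.exp(v)) for k, v in config.beta.items()},
        county_latent_log_mean=dict(zip(ids, latent.tolist())),
    )
    return df, truth


def generate_system_inventory(config: SyntheticConfig, counties: pd.DataFrame) -> pd.DataFrame:
    """Water-system inventory: one row per (system, county served).

    Populations served are log-uniform; each county's public-water-reliant
    population is derived from its systems' total so that the coverage
    fraction is uniform on (coverage_lo, coverage_hi) — counties drawn below
    0.5 will later fail the 50% coverage filter, emulating counties with
    incomplete monitoring representation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_cty = len(counties)
    n_sys_per = 1 + rng.poisson(max(config.systems_per_county_mean - 1.0, 0.0), size=n_cty)
    county_idx = np.repeat(np.arange(n_cty), n_sys_per)
    n_sys = len(county_idx)

    pop_served = np.exp(
        rng.uniform(np.log(config.pop_min), np.log(config.pop_max), size=n_sys)
    ).round().astype(int)
    groundwater = rng.random(n_sys) < config.frac_groundwater_systems
    tribal = rng.random(n_sys) < config.frac_tribal
    correctional = rng.random(n_sys) < config.frac_correctional
    has_report = rng.random(n_sys) >= config.frac_fluoridation_missing
    fluoridated = np.where(
        has_report, (rng.random(n_sys) < config.frac_fluoridated).astype(float), np.nan
    )

    inv = pd.DataFrame(
        {
            "system_id": [f"S{i:06d}" for i in range(n_sys)],
            "county_id": counties["county_id"].to_numpy()[county_idx],
            "population_served": pop_served,
            "source_type": np.where(groundwater, "groundwater", "surface"),
            "region": counties["region"].to_numpy()[county_idx],
            "cluster": counties["cluster"].to_numpy()[county_idx],
            "tribal": tribal,
            "correctional": correctional,
            "fluoridation_reported": fluoridated,
        }
    )
    inv["size_category"] = pd.cut(
        inv["population_served"], EPA_SIZE_BINS, labels=EPA_SIZE_LABELS
    ).astype(str)

    if config.multi_county_frac > 0:
        # duplicate a sampled subset of systems into an adjacent grid county
        n_multi = int(round(config.multi_county_frac * n_sys))
        pick = rng.choice(n_sys, size=n_multi, replace=False)
        cmap = counties.set_index("county_id")
        nc = config.n_county_cols
        dup_rows = []
        for i in pick:
            cid = inv.at[i, "county_id"]
            r, c = int(cmap.at[cid, "grid_row"]), int(cmap.at[cid, "grid_col"])
            c2 = c + 1 if c + 1 < nc else c - 1
            cid2 = _county_id(r, c2, nc)
            row = inv.loc[i].copy()
            row["county_id"] = cid2
            row["region"] = cmap.at[cid2, "region"]
            row["cluster"] = cmap.at[cid2, "cluster"]
            dup_rows.append(row)
        inv = pd.concat([inv, pd.DataFrame(dup_rows)], ignore_index=True)
    return inv


def _system_log_means(config, inventory, latent_by_county, rng):
    """Per-system latent log concentration with fluoridation boost."""
    systems = inventory.drop_duplicates("system_id")
    base = (
        systems["county_id"].map(latent_by_county).to_numpy()
        + rng.normal(0.0, config.sigma_cws, size=len(systems))
    )
    conc = np.exp(base)
    boosted = systems["fluoridation_reported"].fillna(0.0).to_numpy() > 0
    lift = config.fluoridation_strength * np.maximum(
        0.0, config.fluoridation_setpoint - conc
    )
    conc = np.where(boosted, conc + lift, conc)
    return pd.Series(np.log(conc), index=systems["system_id"].to_numpy())


def generate_monitoring_records(
    config: SyntheticConfig,
    inventory: pd.DataFrame,
    latent_by_county: pd.Series | dict,
) -> pd.DataFrame:
    """Compliance monitoring records with censoring, units and raw flags.

    Groundwater systems get one scheduled record per three-year compliance
    window; surface systems one per calendar year; every system additionally
    receives a Poisson number of extra records in random years.  Values below
    the record LOD are flagged nondetect with the value blanked.
    """
    if len(inventory) == 0:
        raise ValueError("inventory is empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    latent_by_county = pd.Series(latent_by_county)
    sys_log = _system_log_means(config, inventory, latent_by_county, rng)

    systems = inventory.drop_duplicates("system_id").set_index("system_id")
    sys_ids = systems.index.to_numpy()
    n_sys = len(sys_ids)
    y0, y1 = config.years
    all_years = np.arange(y0, y1 + 1)

    rec_sys: list[np.ndarray] = []
    rec_year: list[np.ndarray] = []

    gw = (systems["source_type"] == "groundwater").to_numpy()
    # scheduled records: per three-year window for groundwater, yearly otherwise
    windows = [(y, min(y + 2, y1)) for y in range(y0, y1 + 1, 3)]
    n_gw = int(gw.sum())
    for lo, hi in windows:
        yrs = lo + rng.integers(0, hi - lo + 1, size=n_gw)
        rec_sys.append(sys_ids[gw])
        rec_year.append(yrs)
    n_sw = int((~gw).sum())
    if n_sw:
        rec_sys.append(np.repeat(sys_ids[~gw], len(all_years)))
        rec_year.append(np.tile(all_years, n_sw))
    extra = rng.poisson(config.extra_records_mean, size=n_sys)
    if extra.sum():
        rec_sys.append(np.repeat(sys_ids, extra))
        rec_year.append(rng.choice(all_years, size=int(extra.sum())))

    sys_col = np.concatenate(rec_sys)
    year_col = np.concatenate(rec_year).astype(int)
    n_rec = len(sys_col)
    order = np.lexsort((year_col, sys_col))
    sys_col, year_col = sys_col[order], year_col[order]

    mu = sys_log.loc[sys_col].to_numpy()
    value = np.exp(mu + rng.normal(0.0, config.sigma_record, size=n_rec))
    raw = rng.random(n_rec) < config.frac_raw_samples
    value = np.where(raw, value * config.raw_bias, value)

    lods = np.atleast_1d(np.asarray(config.lod_ug_l, dtype=float))
    lod = lods[rng.integers(0, len(lods), size=n_rec)] if len(lods) > 1 else np.full(n_rec, lods[0])
    detected = value >= lod
    mg = rng.random(n_rec) < config.frac_mg_l

    month = rng.integers(1, 13, size=n_rec)
    day = rng.integers(1, 29, size=n_rec)
    dates = [f"{y}-{m:02d}-{d:02d}" for y, m, d in zip(year_col, month, day)]

    out_value = np.where(detected, value, np.nan)
    scale = np.where(mg, 1e-3, 1.0)
    return pd.DataFrame(
        {
            "system_id": sys_col,
            "sample_date": dates,
            "value": out_value * scale,
            "units": np.where(mg, "mg/L", "ug/L"),
            "lod": lod * scale,
            "detected": detected,
            "sample_type": np.where(raw, "raw", "treated"),
        }
    )


def simulate(config: SyntheticConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full generator; optionally write the four CSVs plus truth JSON.

    Returns a dict with keys ``records``, ``inventory``, ``counties``,
    ``adjacency`` (DataFrames) and ``truth`` (:class:`SyntheticTruth`).
    Identical config (including seed) yields byte-identical outputs.
    """
    config.validate()
    edges = generate_grid_adjacency(config.n_county_rows, config.n_county_cols)
    counties, truth = generate_county_covariates(config, edges)
    inventory = generate_system_inventory(config, counties)
    latent = counties.set_index("county_id")["latent_log_mean"]
    records = generate_monitoring_records(config, inventory, latent)

    # public-water-reliant denominator derived from realized served totals
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    served = inventory.groupby("county_id")["population_served"].sum()
    cov = rng.uniform(config.coverage_lo, config.coverage_hi, size=len(counties))
    total_served = counties["county_id"].map(served).fillna(0.0).to_numpy()
    counties = counties.copy()
    counties["public_water_population"] = np.round(
        np.where(total_served > 0, total_served / cov, counties["population"] * 0.8)
    ).astype(int)

    adjacency = pd.DataFrame(edges, columns=["county_a", "county_b"])
    result = {
        "records": records,
        "inventory": inventory,
        "counties": counties,
        "adjacency": adjacency,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False)
        inventory.to_csv(out / "inventory.csv", index=False)
        counties.drop(columns=["latent_log_mean"]).to_csv(out / "counties.csv", index=False)
        adjacency.to_csv(out / "adjacency.csv", index=False)
        truth.to_json(out / "truth.json")
    return result
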