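# Input and output table schemas

All files are UTF-8 CSV with a header row (RFC 4180 quoting).  Concentration
units are µg/L after standardization; raw monitoring records may mix mg/L
and µg/L.

## Inputs

### records.csv — compliance monitoring records

| column | type | meaning |
|---|---|---|
| `system_id` | str | water system identifier |
| `sample_date` | ISO date | collection date |
| `value` | float | concentration in `units`; blank for nondetects |
| `units` | {`mg/L`, `ug/L`} | reporting units for `value` and `lod` |
| `lod` | float | record-specific limit of detection, same units |
| `detected` | bool | False = left-censored below `lod` |
| `sample_type` | {`treated`, `raw`} | finished vs untreated water |

### inventory.csv — water-system inventory (one row per system-county pair)

| column | type | meaning |
|---|---|---|
| `system_id` | str | system identifier |
| `county_id` | str | a county the system serves |
| `population_served` | int | persons served (full count per county row) |
| `source_type` | {`groundwater`, `surface`} | source water |
| `region` | str | one of 8 regions |
| `cluster` | str | one of 8 sociodemographic county clusters |
| `tribal`, `correctional` | bool | system flags |
| `fluoridation_reported` | 0/1/blank | manual fluoridation report; blank = unreported |
| `size_category` | str | EPA population-served category (`<=500`, `501-3300`, `3301-10000`, `>10000`) |

### counties.csv — county covariates

`county_id`, `grid_row`, `grid_col`, `region`, `cluster`, `population`,
`public_water_population` (denominator of the coverage filter), `density`
(persons per square mile), `svi` (social vulnerability score in [0,1]),
`pct_groundwater` (% of public water from groundwater),
`pct_hispanic`, `pct_nh_black`, `pct_aian`, `pct_nh_white` (composition
percents summing to ≤ 100), and `n_<group>` resident counts.

### adjacency.csv — queen contiguity edge list

`county_a`, `county_b`: undirected neighbor pairs; counties absent from the
edge list are islands.

## Outputs

- `cws_estimates.csv`: `system_id`, `mean_6yr` (µg/L), `n_years`,
  `any_raw_override`, `n_records`, `n_nondetect`.
- `county_estimates.csv`: `county_id`, `weighted_mean`, `weighted_p90`,
  `weighted_p95` (µg/L), `n_systems`, `coverage_fraction`,
  `pct_fluoridated`, `status` ∈ {`included`, `inadequate`, `no_data`}.
- `table1.csv`: per grouping × stratum: n, exceedance counts/percents per
  threshold, mean with 95% CI, P90/P95, population served, Kruskal–Wallis p.
- `table2.csv`: analysis-set descriptives (mean/SD per subset).
- `table3.csv`: per group × model: n, GMR with 95% CI, percent change
  triple, spatial parameter λ with SE, log-likelihood, warnings.
- `diagnostics.json`: Moran's I (+ permutation p), LM-lag/LM-error per group.
- `qc_log.txt`: dropped-record and excluded-county accounting.
- `truth.json` (synthetic runs): planted coefficients, λ, per-county latent
  log-means.
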