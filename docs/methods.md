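# Methods

## The estimation problem

Community water systems (CWSs) report fluoride compliance monitoring records
to state primacy agencies; each record is a concentration (mg/L or µg/L), a
record-specific limit of detection (LOD), a detect flag, and a treated/raw
indicator. The package turns such records into chronic exposure estimates and
asks whether county racial/ethnic composition is associated with them once
spatial structure is accounted for.

The chain has four stages:

1. **CWS estimates.** Units are standardized to µg/L. Left-censored
   nondetects are substituted at LOD/√2 — the standard single-value
   substitution for lognormal-ish environmental data at moderate censoring
   rates. Records are averaged within system-calendar-year; when a year has
   both treated and raw samples and the raw mean is higher, only treated
   samples are used (consumers drink finished water). Years with only raw
   samples use the raw mean, since the rule is an override, not an exclusion.
   Yearly means are then averaged unweighted over the analysis window
   (2006–2011 by default) into a six-year mean per system.

2. **County aggregation.** Each county's estimate is the population-weighted
   combination of the systems serving it: weight = population served /
   total served in the county. We report the weighted mean and weighted 90th
   and 95th percentiles, the latter by the left-continuous cumulative-weight
   rule (smallest value whose cumulative weight reaches q); an interpolating
   estimator is available behind a switch. Counties whose monitored systems
   cover less than 50% of the public-water-reliant population are flagged
   `inadequate` (exactly 50% is kept); counties with no monitored systems
   are `no_data`. A multi-county system contributes its full population
   served to each county it serves — this double-counts population across
   counties, but apportionment shares are not observable, and the same
   convention drives the once-per-cluster duplication in the subgroup table.

3. **Inequality summaries.** Stratified tables report exceedance counts
   above 700 µg/L (USPHS recommended level), 1500 µg/L (WHO guideline) and
   4000 µg/L (EPA MCL), using a strict `>` comparison (configurable),
   percents rounded half-even to one decimal, means with normal-approximation
   95% CIs (±1.96·SD/√n), empirical percentiles with linear interpolation,
   and Kruskal–Wallis tests across strata (mid-ranks with ties correction;
   an all-ties stratum returns H = 0, p = 1 rather than an undefined value).

4. **Spatial models.** Counties are linked by queen contiguity (any shared
   boundary point). Global autocorrelation is checked with Moran's I on the
   untransformed county weighted mean (a log-scale switch exists), with both
   a randomization-variance normal approximation and a permutation test
   (999 relabelings by default, seeded, upper-tailed for clustering).
   Lag-vs-error dependence is screened with Anselin's non-robust LM tests.
   Inference proceeds by maximum-likelihood spatial error regression of log
   county fluoride on composition (percent/10) adjusted for population
   density (per 1000), % groundwater-sourced public water (/100) and social
   vulnerability (Model 1), plus population-weighted % fluoridated (/100)
   (Model 2). Effects are geometric mean ratios GMR = exp(β) per 10
   percentage points, with percent change 100·(GMR−1) rounded half-even to
   integer percent; a 60-point unit (majority-community contrast) is a pure
   rescaling available by configuration.

## Spatial error likelihood

With row-standardized weights W (binary contiguity divided by row degree),
the model is y = Xβ + u, u = λWu + ε, ε ~ N(0, σ²I). For fixed λ the
filtered regression (I−λW)y on (I−λW)X gives β(λ) and σ²(λ) in closed form;
the concentrated log-likelihood adds the Jacobian ln|I−λW| = Σᵢ ln(1−λωᵢ),
where ωᵢ are the (real) eigenvalues of W obtained from the similar symmetric
matrix D^{-1/2}AD^{-1/2} and computed once per weights object. λ is found by
bounded scalar search on (1/ω_min, 1/ω_max) with tolerance 1e-8; a solution
within 1e-5 of a bound is flagged as non-converged. Standard errors come
from the observed information — a central-difference Hessian of the full
log-likelihood in (β, λ, σ²) — with a filtered-GLS fallback for β if the
Hessian is not invertible. Row standardization (rather than binary weights)
is the default throughout because it is what makes the eigen-bounded λ
interval and the interpretation of λ as an autocorrelation-like parameter
well behaved; the binary matrix is retained on the weights object. Islands
(counties with no neighbors, possibly created by analysis-set restriction)
are excluded from spatial fits iteratively, with counts logged.

## Synthetic data: what it emulates and what it does not

The generator produces the four inputs with the statistical structure the
analysis assumes. Counties sit on a rectangular grid with queen adjacency —
this reproduces the contiguity machinery exactly while abstracting from real
county shapes. Composition percents are Dirichlet
(means ≈ 10% Hispanic/Latino, 7% non-Hispanic Black, 2% AIAN, 79%
non-Hispanic White); groundwater reliance, density, vulnerability and
population are drawn to match national county-distribution magnitudes.
The county latent log fluoride is

    m_c = b0 + Σ_g β_g·(pct_g/10) + β_gw·(pct_gw/100) + β_svi·svi
          + region effect + u,     u = λWu + ε,

with defaults b0 = ln(250 µg/L), β_hispanic = ln(1.15), other composition
effects 0, β_gw = 0.5 (geogenic fluoride tracks groundwater reliance),
λ = 0.5, σ_spatial = 0.5. Systems add N(0, σ_cws²) (default 0.3); records
add N(0, σ_record²) (default 0.2). Fluoridation reports are present for 79%
of systems and positive for 24% of those; reporting systems are lifted 60%
of the way toward a 700 µg/L set-point on the concentration scale. A
configured fraction of records (20%) is raw with a ×1.1 bias, exercising the
treated/raw rule; half the records arrive in mg/L, exercising conversion.
The default LOD of 310 µg/L was calibrated once, analytically from the
latent scale, so that ~30% of records are nondetect (measured 30.5% over 20
seeds). Each county's public-water denominator is its realized served total
divided by a Uniform(0.4, 1.1) coverage draw, so about one county in seven
fails the 50% filter. One integer seed drives deterministic per-table
sub-streams; identical configs give byte-identical CSVs.

What the generator does **not** emulate: state-level reporting gaps, well
depth/pH geochemistry, purchased-water network structure, apportionment of
multi-county systems (a flag duplicates the system instead), or any
correlation between fluoridation practice and composition beyond what the
latent model induces. Passing tests therefore demonstrate that the
*machinery* is correct and well calibrated under the assumed generative
model, not that real compliance data satisfy those assumptions.

## Recovery study conditions

Parameter-recovery experiments (planted GMR 1.15 per 10% Hispanic/Latino,
λ = 0.5, 20×20 grid) use a dedicated configuration
(`SyntheticConfig.recovery()`) in which the planted effect is actually
identifiable end-to-end:

- fluoridation boost and region offsets off — both bend the county log-mean
  away from the log-linear model being fit, attenuating β;
- σ_cws = σ_record = 0.1 — log-of-weighted-arithmetic-mean aggregation adds
  county-level noise of order σ_cws when one system dominates the weights,
  which dilutes the spatial signal and attenuates λ;
- LOD = 100 µg/L — heavy substitution pins the lower tail at LOD/√2 and
  flattens the dose–response there;
- coverage ≥ 50% everywhere — randomly deleting counties thins the
  contiguity lattice, and correlation carried through missing neighbors is
  misattributed (measured on the true latent field: mean λ̂ 0.507 on the
  full grid vs 0.455 with 14% of counties removed).

Under these conditions 50 replicates give mean λ̂ ≈ 0.48–0.49 and the
planted GMR inside the fitted 95% CI in ≥ 90% of runs. Under the *default*
conditions the same pipeline still detects the planted positive effect but
with attenuation from the mechanisms above — that contrast is deliberate
and is the main caveat for interpreting real-data coefficients.

## Problem sizes and runtime choices

Simulation-based checks use sizes chosen for tight Monte-Carlo error at
interactive runtimes: type-I error calibration runs 1000 null replicates on
a 10×10 grid (binomial SE ≈ 0.7 percentage points at α = 0.05); recovery
runs 50 end-to-end replicates on the 20×20 grid (~1 s each); Moran
permutation tests default to 999 relabelings. Dense eigendecomposition is
used for the log-determinant (counties number in the low thousands at
most); no sparse machinery is needed at these scales.

## Known limitations

- Single-value LOD/√2 substitution is biased relative to censored maximum
  likelihood at high censoring rates; it is retained as the method under
  test, and its distortion is visible in the recovery analysis above.
- CIs for subgroup means are normal approximations; skewed small strata
  (e.g. correctional systems) would be better served by bootstrap CIs.
- The SEM assumes homoskedastic errors; population-weighted county means
  from different numbers of systems are heteroskedastic in truth.
- The spatial-lag model is screened by the LM test but not estimated; the
  error specification is the analysis default.
- Cubic-spline dose–response checks and region-stratified fits beyond
  configuration subsetting are out of scope.
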