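# Methods

This note documents the models, generators, numerical choices and known
limitations of `topotreeline`, in the order the pipeline runs them.

## Response variable

The response is the **elevation deviation from the site maximum**: for
each study area the highest treeline point is taken as an index of the
locally attainable (temperature-limited) treeline, and every point's
deviation is that maximum minus its own elevation. Deviations are ≥ 0 by
construction, exactly one point per site has deviation 0, and the
site-relative definition removes the confounding latitudinal trend in
absolute treeline elevation. The assumption worth stating plainly: the
highest observed point is treated as the climatic potential, so any
disturbance that lowers *every* point in a site is invisible to this
response.

## Synthetic study areas

The generators emulate the *structure* of mesoscale-atmospheric-model
output for square mountain study areas (default 7 × 7 km at 200 m —
1,225 cells), not its physics. What they reproduce:

- **Terrain** (`TerrainSpec`): superposed sinusoidal ridges/valleys at a
  configurable wavelength (default 2.8 km), rescaled so the smooth
  surface's sampled relief equals `relief_amplitude` exactly (default
  600 m over a ~900–1,500 m base), plus i.i.d. Gaussian cell noise
  (default sd 15 m).
- **Meteorology** (`MetSpec`): hourly series for January and July with a
  cosine diurnal temperature cycle peaking at 15:00, a linear elevational
  lapse (default 6.0 °C km⁻¹ referenced to the DEM minimum), humidity in
  anti-phase with temperature clipped to [5, 100] %, wind increasing with
  topographic exposure (elevation minus the 5 × 5-window mean), a
  half-sine shortwave curve over a fixed daylight window (January
  06:00–21:00, July 08:00–17:00 — Southern-Hemisphere seasonality at
  39–46° S), and net radiation equal to shortwave minus a nocturnal
  longwave magnitude, hence strictly negative at night. Shortwave is
  sampled at mid-hour so every hour inside the daylight window is
  strictly positive and the day/night threshold (see below) recovers the
  window exactly. A per-location aspect-exposure factor (±15 %) and a
  per-day weather factor (±30 % on shortwave, ±15 % on longwave) provide
  the between-location and between-day radiation variability that real
  model output has; without them radiation summaries are constant across
  points and the ordination degenerates. January and July defaults
  (means 14 vs 3 °C, solar peaks 950 vs 450 W m⁻², wind 4 vs 5.5 m s⁻¹,
  wet-day probability 0.35 vs 0.45) are plausible New Zealand mountain
  values chosen once.
- **Noise structure**: Gaussian, independent across hours (default sds:
  1 °C, 0.8 m s⁻¹, 5 %RH). There is deliberately no temporal
  autocorrelation beyond the diurnal cycle — the indices consume means,
  extremes and counts, none of which needs it. Rain is generated per day
  (Bernoulli × Gamma), since only rain-day counts are consumed.
- **Treeline points** (`EffectSpec`): points are placed in the DEM's
  upper elevation band (top quartile by default); the *true* deviation is
  a known linear-plus-step function of local curvature, slope and named
  covariates plus Gaussian noise, and the realized elevation is the band
  maximum minus that deviation. Storing the generating coefficients makes
  parameter-recovery, importance-rank and split-threshold tests possible.
- **Regional covariates**: uniform draws from plausible ranges (growing
  season temperature 9–14 °C, annual precipitation 1,000–9,000 mm,
  earthquake intensity 0–1 g, erosion index 0–10). The erosion index and
  the two winter temperatures among the 17 factors are carried as
  documented stand-in covariates without mechanistic content.

What the generators do **not** emulate: advection, cold-air drainage and
ponding, spatial autocorrelation of weather between locations, aspect
geometry (exposure is a scalar factor, not a sun-angle computation), and
any real landcover. Passing tests therefore demonstrate the correctness
and statistical behaviour of the *analysis chain* under known
conditions, not the realism of any particular mountain's climate.

## Day/night partition and the indices

The hourly equations need daytime/nighttime hour sets; these are defined
by an irradiance threshold (daytime ⇔ SolRad > 1 W m⁻², configurable).
The five indices are computed exactly as printed in the README; points
of note:

- **Winter desiccation** has two defensible hour conventions; the
  default sums over all hours and divides by N_total, with a
  daytime-only numerator selectable (`hour_set="daytime_only"`). Both are
  exposed rather than silently choosing one.
- **Site maxima** (T_max, WS_max) are taken per site × month over all
  locations and hours, keeping January and July indices on comparable
  internal scales within a site.
- Summer desiccation has no floor: sub-zero daytime temperatures can
  make it negative, and it is reported as computed.
- Indices whose averaging set is empty (e.g. photoinhibition of a
  polar-night series) raise `UndefinedIndexError` rather than returning
  a silent zero.

Monthly summaries use absolute monthly extremes (not means of daily
extremes), frost hours as hours below 0 °C, rain days as days with
≥ 0.1 mm, and nighttime longwave as the nighttime mean of −NetRad; none
of these thresholds has a canonical definition in the treeline
literature, so they are package defaults, stated here and configurable
where it matters.

## Ordination

PCA is run on the correlation matrix (columns z-scored with sample SD):
the 20 monthly summary variables mix °C, %, W m⁻² and counts, and
covariance-scale PCA would be dominated by the radiation totals.
Components follow a fixed sign convention — the largest-magnitude
loading of each component is positive — so loadings tables are
bit-reproducible across platforms. The pipeline's PCA stage drops
exactly-constant columns before fitting (synthetic winter humidity
maxima saturate at 100 %); the library-level `standardize` is strict and
raises instead, naming the column.

## Random forest

`DeviationForest` is a bagging loop over scikit-learn
`DecisionTreeRegressor`s with explicit bootstrap/out-of-bag bookkeeping:
n_trees (default 2,000; the pipeline and recovery experiments use 300 at
desk scale), ceil(p/3) candidate variables per split, minimum leaf 5.
Keeping the bagging explicit is what makes the classical per-tree OOB
permutation importance computable: %IncMSE for a variable is the mean
over trees of the relative increase in that tree's OOB MSE after
permuting the variable among its OOB rows, ×100. (This is the
unnormalised form; no division by the standard error across trees.)
Partial dependence uses a 25-point quantile-spaced grid — the stress
indices are skewed, and linear grids waste points in empty tails.

## Conditional inference tree

At each node, the association between every candidate variable and the
response is measured by the absolute Pearson correlation; its null
distribution is built from `n_permutations` (default 9,999) random
relabellings of the response, shared across variables, with the p-value
(1 + #exceedances)/(B + 1). P-values are Bonferroni-adjusted across the
candidate variables with positive variance at the node. If the smallest
adjusted p-value is ≥ α (default 0.05) the node is terminal — this
significance gate replaces pruning. Otherwise the node splits on the
smallest-p variable (ties broken by the stronger correlation) at the
cutpoint maximising the absolute between-group difference in mean
response, subject to `min_node` (default 20) observations per side;
cutpoints are midpoints between adjacent distinct values. Degenerate
nodes (constant response or no valid cutpoint) become terminal.
Predictions return the terminal-node median, the node statistic the
analysis reports. Exceedance counting uses a 1e−12 tolerance so
permutations that tie the observed statistic to rounding error count as
exceedances (conservative).

Type-I behaviour: with 17 independent covariates and a null response,
the Bonferroni-adjusted permutation gate keeps the false-split rate at
or below α; the acceptance experiment measures ~5 % over 200 null
datasets (n = 500).

## Pipeline and reproducibility

Stages communicate only through text files (ESRI ASCII grids, CSV,
JSON) in one output directory. The global seed is fanned out per stage
as `(seed × 1000003 + crc32(stage_tag)) mod 2³¹`, so any stage can be
re-run in isolation and reproduce; per-location meteorological draws are
keyed by `(stage seed, location index)` and are independent of how many
locations precede them. Two runs with identical config and seed produce
byte-identical outputs (the manifest's wall-clock timings excepted).

Problem sizes: the bundled end-to-end configuration uses 2–12 study
areas of 1,225 cells with 50–60 treeline points each and full 31-day
months; the recovery experiments use n = 500–1,000 rows, 20 seeds, and
200 null datasets. These are the package's chosen desk-scale study
conditions; all statistical machinery is size-agnostic.

## Known limitations

- Nearest-cell extraction only; no bilinear resampling or reprojection,
  and coordinates are assumed projected metres.
- The curvature operator is the general (not profile/plan) form.
- The forest offers no conditional importance, so correlated predictors
  share importance in the usual way.
- The conditional inference tree tests only univariate linear
  association; a purely non-monotone effect with zero correlation at the
  root can be missed (the classical framework shares this property for
  the linear statistic).
- `EffectSpec` responses are clipped below at 0 to respect the
  response's definition; strongly negative designed effects are
  therefore truncated rather than reproduced exactly.
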