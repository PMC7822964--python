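# Methods

This note documents the models and procedures implemented in `ssci`, the
defaults chosen where the method leaves room, and what the synthetic-data
generators do and do not emulate.

## Scan geometry and conventions

A terrestrial scanner is modelled on a tripod 1.3 m above local ground,
with a 300° vertical × 360° horizontal field of view (the 60° cone below
the tripod is blind) and a native angular step of 360°/10240 ≈ 0.0352° per
axis. Exported clouds are thinned to 1/16 of the native resolution
(decimation by 4 per angular axis), giving a working step of ~0.1406° and
exactly 2560 azimuth columns. The native step was fixed at 360°/10240 —
rather than exactly 0.035° — so that the 1/16 export yields an integral
sector count and the 1280 cross-section pairs come out exactly.

All modules share one angular convention: azimuth in degrees, counter-
clockwise from +x, in [0, 360); elevation in degrees from the horizontal
plane, positive up. Clouds are scanner-centered Cartesian (meters, z up).

Thinning keeps, per coarse 4×4-step cell, the return closest to the cell's
origin direction (ties by input order), so grids aligned with the native
step survive at exactly every 4th azimuth and elevation index. Whether the
vendor's export decimates returns or re-samples is not public; decimation
by angular cell is our choice. Likewise the vendor's stray-point filters
are proprietary; `filter_stray` is a documented radius/neighbor-count
filter (defaults 0.5 m, 3 neighbors).

## Per-scan metrics

**Cross-sections.** Returns are bucketed into azimuthal sectors of
0.140625°; sector k pairs with sector k+180°. Vertices are (±horizontal
distance, height): the first sector's returns ordered by ascending
elevation, the opposite sector's appended in descending elevation, closed
last-to-first. The scanner position is *not* inserted as a vertex. Pairs
with fewer than 3 returns are skipped and counted.

**FRAC.** `FRAC = 2 ln(0.25 P)/ln A` with perimeter and area from the
shoelace rule on the closed vertex chain. Values are clipped to [1, 2];
polygons with A ≤ 1 m² or P ≤ 4 m leave the logs ill-behaved and are
excluded from the mean rather than imputed (excluded counts are reported).
A square of any side scores exactly 1.

**ENL.** Inverse Simpson index of return counts in 1-m height bins
anchored at `floor(min z)` of the scan — reproducible without a ground
model. ENL equals the occupied-bin count iff occupancy is uniform.

**SSCI.** `MeanFRAC ** ln(ENL)`; the identity is asserted on every emitted
metrics record.

**Openness.** Full apex opening angle 60° (zenith angle ≤ 30°); the wider
reading (zenith ≤ 60°) is a parameter. Return directions are binned into
equal-solid-angle cells (uniform azimuth × cos-zenith grid, ~1° cells);
openness is the fraction of empty cells. The computation accepts either a
filtered or an unfiltered cloud — the caller decides which to pass.

**Basal area.** Bitterlich angle-count sampling: a stem is tallied when
`distance ≤ dbh·50/√BAF`; estimate = BAF × tally (default BAF 2 m²/ha).
Monte-Carlo tests confirm the estimator is unbiased on synthetic stands
when sample points keep every inclusion circle inside the stand.

## Site aggregation and covariates

Scan metrics average to plot means; plot means average to site means with
SE = sd/√n (single-plot sites report SE 0 with a flag). Precipitation
seasonality is the CV (%) of monthly rainfall using the population SD;
note WorldClim's bio15 adds 1 to the mean denominator, so externally
sourced bio15 values differ slightly. Growing season: months with mean
temperature ≥ 5 °C (temperate/boreal) or with precipitation strictly above
half the monthly PET (tropics). Soil variables on the standard depth
intervals (0–5, 5–15, 15–30, 30–60, 60–100 cm) combine with weights
(5, 10, 15, 30, 40)/100 into a 1-m mean; field capacity and nitrogen are
conventionally natural-log-transformed before modelling.

## Model selection

Candidates are all non-empty predictor subsets whose pairwise Pearson |r|
over sites is strictly below 0.7 — the threshold excludes |r| ≥ 0.7
combinations. Each candidate is fitted by OLS and, when a biome column is
present, as a linear mixed model with a biome random intercept. Mixed
models are estimated by maximum likelihood, not REML, because AICc values
are compared across different fixed-effect structures. A model is rejected
when any predictor's p-value is ≥ 0.05 (NaN p-values also reject). AICc is
`−2 ln L + 2k + 2k(k+1)/(n−k−1)` with k counting the intercept, slopes and
residual variance (plus the random-intercept variance for mixed models).
Mixed-model R² is the squared correlation of fitted (fixed + random)
versus observed values.

Moran's I uses inverse great-circle-distance weights (spherical earth,
radius 6371 km), zero diagonal, not row-standardized; coincident sites get
their weight capped at the largest finite weight with a warning. The
p-value is a seeded two-sided permutation test (999 permutations by
default). LOOCV refits the model n times and reports held-out RMSE and R²
as the squared correlation of predictions and observations (the
1 − SSE/SST variant is an option). Biome exclusion refits once per biome
with that biome's sites removed; refits that would leave too few sites are
reported as not evaluable rather than failing.

Site means enter the regressions unweighted; the per-site SEs are carried
for reporting but do not weight the fit.

## Mapping

The sampling grid is built from latitude rings spaced `spacing/111.32`
degrees apart (the equator ring included), with longitude step
`spacing/(111.32 cos lat)` within each ring — adjacent same-ring points are
50 ± 1 km apart by haversine. Ecoregion names pass a case-insensitive
substring filter: must contain one of {forest, woodland, taiga, chaco,
yungas, várzea, campinarana} and none of {steppe, tundra, meadow,
grassland}; both lists are configurable.

The per-biome climate envelope is a Gaussian-product KDE (Scott bandwidth)
over (MAP, seasonality); the 95% highest-density region is thresholded at
the 5th percentile of the density evaluated at the biome's own samples,
which retains 95% of them up to KDE discretization. Biomes with fewer than
30 samples skip the filter rather than fit an unstable density.

`SSCI_pot` is affine in MAP and seasonality. The clamp thresholds default
to (2, 9) — the structural range observed at the calibration sites — and
are configurable because they are defined by the data, not the model. The
mapping stage never hard-codes regression coefficients: they come from a
`StructureClimateResults` best fit or from explicit configuration.

Tukey HSD letters use the insert-and-absorb compact-letter-display
algorithm; ties are broken alphabetically by biome name. The latitudinal
smooth is a cubic B-spline GAM (10 basis functions) with the penalty
weight chosen by statsmodels' generalized cross-validation search; the
search's optimizer start values are seeded so refits are identical.

## Synthetic data

**Scenes and scans.** Trees are stems (opaque vertical cylinders) plus
crown shells (ellipsoid, cone or cylinder) that intercept a beam with
probability `crown_point_density` (default 0.3) — a one-knob stand-in for
foliage that spans open to closed canopies. Scenes are strata of uniform
stem positions at a given density; crowns are drawn inside each stratum's
height band. The ray caster returns the first surface per beam (ground,
stem, or accepted crown hit) on the configured angular grid; no beam
divergence, multiple returns, radiometry, or leaf-angle distributions.
Ground is returned for downward beams so the lowest ENL bin is populated
as in real scans.

The canonical layered/unlayered comparison uses a three-strata stand
(2–5 m shrubs at 300/ha with 0.8–1.5 m crowns, 10–15 m mid-story at 150/ha
with 1.5–2.5 m crowns, 25–30 m overstory at 150/ha with 2.5–4 m crowns)
against a single 25–30 m stratum at 300/ha, on 60×60 m extents — crown
radii scaled to stature, stem densities in the range of closed natural
stands. Paired scans use a 60°-half-angle zenith dome at the 0.14° step:
the dome carries nearly all of the structural signal at a fraction of the
full-hemisphere ray count, which keeps the 100-pair replication affordable;
the full 300° field of view is the default everywhere else. Scan positions
move off stems with 0.3 m clearance, as a field crew would place a tripod.

**Site tables.** `ssci = 2.8 + 0.002·MAP − 0.03·seasonality + ε`,
σ(ε) = 0.67, with MAP ~ U(300, 3500) mm and seasonality ~ U(10, 100) %:
20 sites spanning SSCI ≈ 2–9 with a design R² of 0.90 — field-realistic
magnitudes for primary forests across biomes. Optional extras: independent
distractor covariates (MAT, solar radiation), biome labels with Gaussian
random intercepts, and an exponential-covariance Gaussian residual field
on great-circle distances (the seeded positive control for Moran's I; the
calibrated control uses 80 sites on a continental domain, range 3000 km,
sill 4 — enough spatial information for the permutation test to detect
clustering essentially always). What the generator does *not* emulate:
covariate collinearity structures of real climate data, non-linear
responses, measurement error in SSCI, or uneven site clustering — so
passing tests demonstrate the machinery is correct and calibrated, not
that real forests obey a linear model.

**Rasters.** Seeded constant, gradient, or smooth (low-frequency cosine
mixture) lon/lat fields written as ESRI ASCII grids with 17-significant-
digit values (write/read round trips are bit-exact), plus toy ecoregion
polygon strips whose names exercise both keyword lists.

## Problem sizes and numerical notes

Replicated suites use 100 paired scans (dome grid), 100 twenty-site
tables, 500 Moran null simulations with 499 permutations, 10⁴-point
envelope checks — sizes at which Monte-Carlo error is well inside the
asserted tolerances while a full run stays in the minutes range on one
CPU. Degenerate inputs fail loudly and specifically: empty clouds, origin
points, rank-deficient designs, zero-variance predictors, constant
residuals, degenerate extents. Sector assignment nudges azimuths by 1e-9
steps so returns lying exactly on a sector boundary bin deterministically.

## Known limitations

* Crown shells are hard geometric surfaces with Bernoulli interception;
  real foliage produces partial hits, multiple returns and range noise.
* Ground is flat per scene; terrain is not modelled.
* The mixed-model LOOCV predicts from fixed effects only.
* The ecoregion keyword filter is name-based and inherits the quirks of
  whatever polygon dataset the user supplies.
* ENL bins anchor at the scan's lowest return, so two scans of the same
  stand can shift bin boundaries by up to 1 m.
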