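# ssci — stand structural complexity from terrestrial laser scans

`ssci` quantifies the three-dimensional structural complexity of forest
stands from single hemispherical terrestrial laser scans, models how that
complexity responds to climate across sites, and maps the climate-predicted
*potential* complexity of forested ecoregions. It is written for forest
ecologists and macroecologists who work with TLS point clouds and site-level
climate tables, and it ships synthetic scene/scan/table generators so the
entire pipeline can be exercised and tested without any field data or
raster downloads.

## The index and the models

**SSCI.** A scan (a 3-column `.xyz` cloud, scanner-centered, z up) is split
into 2560 azimuthal sectors of ~0.14°. Each sector and its opposite are
chained into a closed cross-sectional polygon in the vertical cutting plane
(horizon → zenith → opposite horizon). Each polygon's shape complexity is
the fractal-dimension index

    FRAC = 2 ln(0.25 P) / ln A          (P in m, A in m², clipped to [1, 2])

which is 1 for compact outlines and approaches 2 for highly convoluted
ones. The scan's mean FRAC over its 1280 polygon pairs is scaled by
vertical stratification:

    SSCI = MeanFRAC ^ ln(ENL),    ENL = 1 / Σ pᵢ²

where ENL (effective number of layers) is the inverse Simpson index of the
point counts in 1-m height bins. Canopy height (z extent), canopy openness
(gap fraction of a 60° zenith cone) and Bitterlich angle-count basal area
complete the per-scan record; scans aggregate to plot means and plot means
to site means ± SE.

**Climate–structure model.** Site-mean SSCI is regressed on climate/soil
covariates by all-subsets OLS (and optionally biome-random-intercept mixed
models fitted by ML): subsets with any pairwise |r| ≥ 0.7 are never fitted,
models with a non-significant predictor (p ≥ 0.05) are rejected, survivors
are ranked by AICc. Diagnostics: residual Moran's I (inverse great-circle-
distance weights, permutation test), leave-one-out cross-validation, and
whole-biome exclusion refits.

**Mapping.** The best model predicts potential complexity
`SSCI_pot = β₀ + β₁·MAP + β₂·seasonality` over a 50-km geodesic sampling
grid restricted to forest/woodland ecoregions (keyword name filter) and to
each biome's 95% kernel-density climate envelope; predictions outside the
calibrated structural range are reported conservatively as the classes
"≥9" / "≤2". Per-biome summaries use one-way ANOVA with Tukey HSD letters;
the latitudinal profile is a penalized-spline GAM with a 95% band.

## Worked example

Generate a 20-site synthetic table whose SSCI responds linearly to mean
annual precipitation (MAP, mm) and precipitation seasonality (CV %) with
residual SD 0.67 (design R² ≈ 0.90), then run model selection:

```python
from ssci import SiteTableSpec, StructureClimateModel, make_site_table

table = make_site_table(SiteTableSpec(seed=3))
model = StructureClimateModel.from_dataframe(
    table,
    predictors=["MAP", "prec_seasonality", "MAT", "solar_radiation"],
    forms=("ols",),
)
results = model.fit()
print(results.summary())
rmse, r2 = results.loocv()
print(f"\nLOOCV: RMSE={rmse:.2f}, R2={r2:.2f}")
```

prints

```
Climate-structure model selection
======================================================================
response: ssci    sites: 20    candidates: 15 (12 rejected)

form             predictors    r2   aicc  delta_aicc  rmse  morans_i
  lm MAP + prec_seasonality 0.888 46.560       0.000 0.594     0.016
  lm                    MAP 0.637 66.884      20.323 1.068    -0.095
  lm       prec_seasonality 0.345 78.661      32.100 1.433     0.053

best model: lm: MAP + prec_seasonality
coefficients (SE):
                 const   3.81962 (0.523), p=1.25e-06
                   MAP   0.00164287 (0.000181), p=6.41e-08
      prec_seasonality  -0.0313167 (0.00508), p=1.04e-05
residual Moran's I: 0.016 (p=0.318)

LOOCV: RMSE=0.71, R2=0.84
```

Of the 15 collinearity-free candidate models, 12 are rejected because a
predictor is non-significant (including every model containing the two
distractor covariates); the generating MAP + seasonality pair wins by a
wide AICc margin, explains 89% of the variance, cross-validates with a
held-out RMSE close to the generating noise SD, and leaves no spatial
autocorrelation in the residuals.

The same flow works from the shell:

```sh
ssci simulate site-table --seed 3 --out sites.csv
ssci fit --table sites.csv --pool MAP,prec_seasonality,MAT --out ranking.csv
ssci simulate rasters --out-dir layers --seed 2
ssci map predict --map-raster layers/MAP.asc \
    --seasonality-raster layers/prec_seasonality.asc \
    --intercept 2.8 --coef-map 0.002 --coef-seasonality -0.03 \
    --out-prefix sscipot
```

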