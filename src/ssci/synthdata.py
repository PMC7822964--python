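"""Synthetic site tables and climate rasters with known statistical structure.

``make_site_table`` emulates the study design behind the climate–structure
regression: a handful of sites spread across the globe whose structural
complexity responds linearly to mean annual precipitation and precipitation
seasonality, with optional biome random intercepts and optional spatially
autocorrelated residuals (the positive control for Moran's I).

Default generating coefficients were chosen once to mirror field-realistic
conditions: 20 sites, SSCI between ~2 and ~9, residual SD 0.67 giving a
design R^2 of ~0.90 for the true predictor pair.

``make_climate_rasters`` builds small, smooth, seeded lon/lat rasters plus
toy ecoregion polygons whose names exercise the forest/woodland keyword
filter of the mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import pairwise_haversine_km
from .raster import Raster


@dataclass
class SpatialAutocorrelation:
    """Exponential-covariance Gaussian residual field: cov(d) = sill *
    exp(-d / range_km) on great-circle distances."""

    range_km: float
    sill: float

    def __post_init__(self):
        if self.range_km <= 0 or self.sill < 0:
            raise ValueError("need range_km > 0 and sill >= 0")


@dataclass
class SiteTableSpec:
    """Recipe for a synthetic site covariate/response table.

    The response is ``ssci = beta0 + beta_map * MAP
    + beta_seasonality * seasonality (+ biome intercept + spatial field)
    + N(0, noise_sd)``; covariates are independent uniforms on their ranges.
    Extra covariates act as distractors for model selection.
    """

    n_sites: int = 20
    beta0: float = 2.8
    beta_map: float = 0.002
    beta_seasonality: float = -0.03
    noise_sd: float = 0.67
    covariate_ranges: dict = field(default_factory=lambda: {
        "MAP": (300.0, 3500.0),
        "prec_seasonality": (10.0, 100.0),
    })
    extra_covariate_ranges: dict = field(default_factory=lambda: {
        "MAT": (-5.0, 27.0),
        "solar_radiation": (8000.0, 22000.0),
    })
    biome_labels: list | None = None
    biome_intercept_sd: float = 0.0
    spatial_autocorrelation: SpatialAutocorrelation | None = None
    lon_range: tuple[float, float] = (-170.0, 170.0)
    lat_range: tuple[float, float] = (-55.0, 65.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("MAP", "prec_seasonality"):
            if name not in self.covariate_ranges:
                raise ValueError(f"covariate_ranges must include {name!r}")
        for name, (lo, hi) in {**self.covariate_ranges,
                               **self.extra_covariate_ranges}.items():
            if not hi > lo:
                raise ValueError(f"degenerate range for {name!r}")
        if self.biome_labels is not None and \
                len(set(self.biome_labels)) > self.n_sites:
            raise ValueError("more biome labels than sites")

    @property
    def design_r2(self) -> float:
        """R^2 implied by the uniform covariates and the iid noise alone."""
        var = 0.0
        for name, beta in (("MAP", self.beta_map),
                           ("prec_seasonality", self.beta_seasonality)):
            lo, hi = self.covariate_ranges[name]
            var += beta ** 2 * (hi - lo) ** 2 / 12.0
        return var / (var + self.noise_sd ** 2)


def make_site_table(spec: SiteTableSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate the site table; deterministic for a given (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_sites
    data: dict = {"site_id": [f"site_{i:02d}" for i in range(n)]}
    data["lon"] = rng.uniform(*spec.lon_range, n)
    data["lat"] = rng.uniform(*spec.lat_range, n)
    for name, (lo, hi) in {**spec.covariate_ranges,
                           **spec.extra_covariate_ranges}.items():
        data[name] = rng.uniform(lo, hi, n)

    response = (
        spec.beta0
        + spec.beta_map * data["MAP"]
        + spec.beta_seasonality * data["prec_seasonality"]
    )

    if spec.biome_labels is not None:
        labels = np.asarray(spec.biome_labels, dtype=object)
        biome = labels[np.arange(n) % len(labels)]
        rng.shuffle(biome)
        data["biome"] = biome
        if spec.biome_intercept_sd > 0:
            unique = np.unique(labels)
            intercepts = dict(zip(
                unique, rng.normal(0.0, spec.biome_intercept_sd, unique.size)
            ))
            response = response + np.array([intercepts[b] for b in biome])

    if spec.spatial_autocorrelation is not None:
        sa = spec.spatial_autocorrelation
        d = pairwise_haversine_km(data["lon"], data["lat"])
        cov = sa.sill * np.exp(-d / sa.range_km)
        cov[np.diag_indices(n)] += 1e-9 * max(sa.sill, 1.0)
        response = response + rng.multivariate_normal(
            np.zeros(n), cov, method="cholesky"
        )

    if spec.noise_sd > 0:
        response = response + rng.normal(0.0, spec.noise_sd, n)

    data["ssci"] = response
    return pd.DataFrame(data)


_ECOREGION_NAMES = [
    ("Borneo lowland rain forests", "tropical_moist"),
    ("Zambezian Baikiaea woodlands", "savanna_woodland"),
    ("Scandinavian and Russian taiga", "boreal"),
    ("East European forest steppe", "temperate_broadleaf"),
    ("Central US forest-grassland transition", "temperate_broadleaf"),
    ("Valdivian temperate forests", "temperate_broadleaf"),
    ("Patagonian grasslands", "grassland"),
    ("Carpathian montane forests", "temperate_conifer"),
]


def make_climate_rasters(
    extent: tuple[float, float, float, float],
    resolution: float,
    fields: dict | None = None,
    seed: int = 0,
) -> tuple[dict[str, Raster], list[tuple[object, dict]]]:
    """Seeded climate rasters plus toy ecoregion polygons.

    ``extent`` is (lon_min, lat_min, lon_max, lat_max).  ``fields`` maps a
    field name (default ``MAP`` and ``prec_seasonality``) to one of

    * ``{"kind": "constant", "value": v}``
    * ``{"kind": "gradient", "intercept": a, "per_lon": b, "per_lat": c}`` —
      evaluated at pixel centers,
    * ``{"kind": "smooth", "range": (lo, hi)}`` — a seeded smooth random
      field rescaled into the range.

    Returns ``(rasters, ecoregion_features)`` where features are
    (shapely polygon, {"name", "biome"}) pairs tiling the extent with
    ecoregion-style names, some of which hit the include/exclude keyword
    lists of the mapping stage.
    """
    lon_min, lat_min, lon_max, lat_max = extent
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate raster extent")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    fields = fields or {
        "MAP": {"kind": "smooth", "range": (300.0, 3500.0)},
        "prec_seasonality": {"kind": "smooth", "range": (10.0, 100.0)},
    }
    ncols = max(1, int(round((lon_max - lon_min) / resolution)))
    nrows = max(1, int(round((lat_max - lat_min) / resolution)))
    rng = np.random.default_rng(seed)
    lon = lon_min + (np.arange(ncols) + 0.5) * resolution
    lat = (lat_min + nrows * resolution) - (np.arange(nrows) + 0.5) * resolution
    lon_grid, lat_grid = np.meshgrid(lon, lat)

    rasters: dict[str, Raster] = {}
    for name, fs in fields.items():
        kind = fs.get("kind", "smooth")
        if kind == "constant":
            data = np.full((nrows, ncols), float(fs["value"]))
        elif kind == "gradient":
            data = (fs.get("intercept", 0.0)
                    + fs.get("per_lon", 0.0) * lon_grid
                    + fs.get("per_lat", 0.0) * lat_grid)
        elif kind == "smooth":
            lo, hi = fs["range"]
            # sum of a few random low-frequency cosine modes -> smooth field
            raw = np.zeros((nrows, ncols))
            for _ in range(6):
                fx, fy = rng.uniform(0.2, 1.5, 2)
                phase = rng.uniform(0, 2 * np.pi)
                amp = rng.uniform(0.5, 1.0)
                span_x = max(lon_max - lon_min, 1e-9)
                span_y = max(lat_max - lat_min, 1e-9)
                raw += amp * np.cos(
                    2 * np.pi * (fx * (lon_grid - lon_min) / span_x
                                 + fy * (lat_grid - lat_min) / span_y)
                    + phase
                )
            rmin, rmax = raw.min(), raw.max()
            if rmax - rmin < 1e-12:
                data = np.full_like(raw, 0.5 * (lo + hi))
            else:
                data = lo + (raw - rmin) / (rmax - rmin) * (hi - lo)
        else:
            raise ValueError(f"unknown field kind {kind!r}")
        rasters[name] = Raster(data=data, xllcorner=lon_min,
                               yllcorner=lat_min, cellsize=resolution)

    # tile the extent into vertical strips of toy ecoregions
    features = []
    n_strips = min(len(_ECOREGION_NAMES), max(2, ncols // 2))
    edges = np.linspace(lon_min, lon_max, n_strips + 1)
    for i in range(n_strips):
        name, biome = _ECOREGION_NAMES[i % len(_ECOREGION_NAMES)]
        features.append(
            (box(edges[i], lat_min, edges[i + 1], lat_max),
             {"name": name, "biome": biome})
        )
    return rasters, features
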