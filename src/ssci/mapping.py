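"""Potential structural complexity over forested ecoregions.

The mapping stage turns a fitted climate–structure model into a spatial
prediction of the *potential* stand structural complexity (SSCI_pot) — the
climate-defined climax a site could reach absent disturbance:

1. a geodesic sampling grid (latitude rings a fixed distance apart) is laid
   over the ecoregions of interest;
2. samples are kept only in forest/woodland ecoregions, by case-insensitive
   keyword inclusion/exclusion on ecoregion names;
3. per biome, a 95% highest-density region of the (MAP, precipitation
   seasonality) kernel density removes climatically marginal samples so the
   regression is never extrapolated far outside its support;
4. SSCI_pot is predicted linearly from MAP and seasonality; predictions
   beyond the structural range observed at the calibration sites are
   conservatively reported as the clamp classes ">=9" and "<=2";
5. summaries: per-biome distribution with one-way ANOVA + Tukey HSD compact
   letters, and a latitudinal penalized-spline (GAM) smooth with a 95%
   confidence band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .climatemodel import ModelFit
from .geo import KM_PER_DEGREE
from .raster import Raster

#: Keyword lists defining forest/woodland ecoregions by name.
INCLUDE_KEYWORDS = (
    "forest", "woodland", "taiga", "chaco", "yungas", "várzea", "campinarana",
)
EXCLUDE_KEYWORDS = ("steppe", "tundra", "meadow", "grassland")

CLAMP_HIGH_LABEL = ">=9"
CLAMP_LOW_LABEL = "<=2"


def sample_grid(
    region=None,
    spacing_km: float = 50.0,
    lat_range: tuple[float, float] = (-90.0, 90.0),
) -> pd.DataFrame:
    """Systematic geodesic sampling grid with ``spacing_km`` between points.

    Latitude rings are ``spacing_km`` apart (the equator ring is always one
    of them); within a ring the longitude step is
    ``spacing_km / (111.32 cos lat)`` degrees.  If ``region`` (a shapely
    geometry or an iterable of them) is given, only points inside it are
    returned; an empty region yields an empty frame with a warning.
    """
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")
    dlat = spacing_km / KM_PER_DEGREE
    lat_lo, lat_hi = lat_range
    ks = np.arange(int(np.ceil(lat_lo / dlat)), int(np.floor(lat_hi / dlat)) + 1)
    lons_all, lats_all = [], []
    for k in ks:
        lat = k * dlat
        if abs(lat) >= 90.0:
            continue
        n_lon = int(np.floor(360.0 * KM_PER_DEGREE * np.cos(np.radians(lat))
                             / spacing_km))
        if n_lon < 1:
            continue
        step = spacing_km / (KM_PER_DEGREE * np.cos(np.radians(lat)))
        lons = -180.0 + np.arange(n_lon) * step
        lons_all.append(lons)
        lats_all.append(np.full(n_lon, lat))
    lons = np.concatenate(lons_all) if lons_all else np.empty(0)
    lats = np.concatenate(lats_all) if lats_all else np.empty(0)
    df = pd.DataFrame({"lon": lons, "lat": lats})
    if region is not None:
        geom = region if isinstance(region, shapely.Geometry) \
            else shapely.union_all(list(region))
        if geom.is_empty:
            warnings.warn("sampling region is empty", stacklevel=2)
            return df.iloc[:0].reset_index(drop=True)
        inside = shapely.contains_xy(geom, df["lon"].to_numpy(),
                                     df["lat"].to_numpy())
        df = df[inside].reset_index(drop=True)
        if df.empty:
            warnings.warn("no grid point falls inside the region", stacklevel=2)
    return df


def assign_ecoregions(samples: pd.DataFrame, features) -> pd.DataFrame:
    """Attach ``ecoregion`` and ``biome`` columns from (geometry, props)
    pairs; samples outside every polygon get NaN."""
    out = samples.copy()
    names = np.full(len(out), None, dtype=object)
    biomes = np.full(len(out), None, dtype=object)
    pts_x = out["lon"].to_numpy()
    pts_y = out["lat"].to_numpy()
    for geom, props in features:
        mask = shapely.contains_xy(geom, pts_x, pts_y) & pd.isna(names)
        names[mask] = props.get("name")
        biomes[mask] = props.get("biome")
    out["ecoregion"] = names
    out["biome"] = biomes
    return out


def ecoregion_keyword_filter(
    samples: pd.DataFrame,
    include=INCLUDE_KEYWORDS,
    exclude=EXCLUDE_KEYWORDS,
    name_col: str = "ecoregion",
) -> pd.DataFrame:
    """Keep samples whose ecoregion name contains an inclusion keyword and
    none of the exclusion keywords (case-insensitive substrings)."""
    names = samples[name_col].fillna("").astype(str).str.lower()
    keep = names.apply(lambda s: any(k in s for k in include)
                       and not any(k in s for k in exclude))
    return samples[keep].reset_index(drop=True)


@dataclass
class EnvelopeModel:
    """Highest-density region of a biome's (MAP, seasonality) distribution."""

    biome: object
    kde: stats.gaussian_kde
    threshold: float
    mass: float = 0.95

    def contains(self, map_mm, seasonality) -> np.ndarray:
        pts = np.vstack([np.asarray(map_mm, dtype=float),
                         np.asarray(seasonality, dtype=float)])
        return self.kde(pts) >= self.threshold


def fit_envelope(
    samples: pd.DataFrame,
    biome=None,
    mass: float = 0.95,
    map_col: str = "MAP",
    seas_col: str = "prec_seasonality",
    bw_method="scott",
    min_samples: int = 30,
) -> EnvelopeModel:
    """Fit the ``mass`` highest-density region of one biome's climate cloud.

    Gaussian product kernel; the density threshold is the
    ``(1 - mass)``-quantile of the density evaluated at the samples, so the
    region holds the stated mass fraction up to KDE discretization.
    """
    if len(samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples for a stable envelope, "
            f"got {len(samples)}"
        )
    pts = np.vstack([samples[map_col].to_numpy(dtype=float),
                     samples[seas_col].to_numpy(dtype=float)])
    kde = stats.gaussian_kde(pts, bw_method=bw_method)
    dens = kde(pts)
    threshold = float(np.quantile(dens, 1.0 - mass))
    return EnvelopeModel(biome=biome, kde=kde, threshold=threshold, mass=mass)


def apply_envelope(
    samples: pd.DataFrame,
    model: EnvelopeModel,
    map_col: str = "MAP",
    seas_col: str = "prec_seasonality",
) -> pd.DataFrame:
    """Flag samples inside the envelope (column ``inside_envelope``)."""
    out = samples.copy()
    out["inside_envelope"] = model.contains(out[map_col], out[seas_col])
    return out


def envelope_filter_by_biome(
    samples: pd.DataFrame,
    biome_col: str = "biome",
    mass: float = 0.95,
    **kwargs,
) -> pd.DataFrame:
    """Fit and apply the climate envelope per biome; biomes too small for a
    stable density keep all their samples (flagged inside)."""
    parts = []
    for b, grp in samples.groupby(biome_col, sort=True):
        try:
            env = fit_envelope(grp, biome=b, mass=mass, **kwargs)
        except ValueError:
            grp = grp.copy()
            grp["inside_envelope"] = True
            parts.append(grp)
            continue
        parts.append(apply_envelope(grp, env))
    return pd.concat(parts).sort_index()


@dataclass
class PredictionModel:
    """Linear SSCI_pot predictor with conservative clamping.

    ``ssci_pot = intercept + coef_map * MAP + coef_seasonality * seasonality``;
    predictions above ``clamp_high`` (the highest site SSCI observed during
    calibration) or below ``clamp_low`` are reported as classes instead of
    values.
    """

    intercept: float
    coef_map: float
    coef_seasonality: float
    clamp_low: float = 2.0
    clamp_high: float = 9.0

    def __post_init__(self):
        for v in (self.intercept, self.coef_map, self.coef_seasonality):
            if not np.isfinite(v):
                raise ValueError("prediction coefficients must be finite")

    @classmethod
    def from_fit(cls, fit: ModelFit,
                 map_name: str = "MAP",
                 seas_name: str = "prec_seasonality",
                 **kwargs) -> "PredictionModel":
        params = fit.params
        return cls(
            intercept=float(params.get("const", 0.0)),
            coef_map=float(params[map_name]),
            coef_seasonality=float(params[seas_name]),
            **kwargs,
        )

    def value(self, map_mm, seasonality):
        return (self.intercept + self.coef_map * np.asarray(map_mm, dtype=float)
                + self.coef_seasonality * np.asarray(seasonality, dtype=float))


def predict_sscipot(
    samples: pd.DataFrame,
    model: PredictionModel,
    map_col: str = "MAP",
    seas_col: str = "prec_seasonality",
) -> pd.DataFrame:
    """Predict SSCI_pot per sample; adds ``ssci_pot`` (the linear value) and
    ``ssci_pot_class`` ("", ">=9" or "<=2")."""
    out = samples.copy()
    v = model.value(out[map_col], out[seas_col])
    out["ssci_pot"] = v
    cls = np.where(v > model.clamp_high, CLAMP_HIGH_LABEL,
                   np.where(v < model.clamp_low, CLAMP_LOW_LABEL, ""))
    out["ssci_pot_class"] = cls
    return out


def predict_sscipot_raster(
    map_raster: Raster,
    seas_raster: Raster,
    model: PredictionModel,
) -> tuple[Raster, Raster]:
    """Pixelwise SSCI_pot prediction.

    Returns ``(value, clamp_class)`` rasters on the MAP grid: the class band
    is 0 inside the calibrated range, +1 where the value exceeds
    ``clamp_high``, -1 below ``clamp_low``; pixels with a missing covariate
    are nodata in both bands.
    """
    if map_raster.shape != seas_raster.shape:
        raise ValueError("covariate rasters must share a grid")
    m = map_raster.data
    s = seas_raster.data
    missing = (m == map_raster.nodata) | (s == seas_raster.nodata) | \
        ~np.isfinite(m) | ~np.isfinite(s)
    v = model.value(m, s)
    cls = np.where(v > model.clamp_high, 1.0,
                   np.where(v < model.clamp_low, -1.0, 0.0))
    v = np.where(missing, map_raster.nodata, v)
    cls = np.where(missing, map_raster.nodata, cls)
    geo = dict(xllcorner=map_raster.xllcorner, yllcorner=map_raster.yllcorner,
               cellsize=map_raster.cellsize, nodata=map_raster.nodata)
    return Raster(v, **geo), Raster(cls, **geo)


def _compact_letters(groups, different: set[tuple]) -> dict:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different; ``different``
    holds the significantly different (a, b) pairs.  Ties in letter order
    are broken alphabetically by group name.
    """
    groups = sorted(groups)
    sets = [set(groups)]
    for a, b in sorted(different):
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend((s - {a}, s - {b}))
            else:
                new_sets.append(s)
        # absorb subsets and duplicates
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


def biome_summary(
    samples: pd.DataFrame,
    value_col: str = "ssci_pot",
    biome_col: str = "biome",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float | None]:
    """Per-biome distribution summary with Tukey HSD grouping letters.

    Returns ``(summary, anova_p)``: one row per biome (n, mean, median,
    IQR bounds, letter), plus the one-way ANOVA p-value (None with a single
    biome, in which case no test is run).
    """
    groups = {b: g[value_col].to_numpy(dtype=float)
              for b, g in samples.groupby(biome_col, sort=True)}
    rows = [
        {
            "biome": b, "n": v.size, "mean": v.mean(),
            "median": float(np.median(v)),
            "q25": float(np.quantile(v, 0.25)),
            "q75": float(np.quantile(v, 0.75)),
        }
        for b, v in groups.items()
    ]
    summary = pd.DataFrame(rows)
    if len(groups) < 2:
        summary["letters"] = "a"
        return summary, None
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("each biome needs at least 2 samples for the test")
    _, anova_p = stats.f_oneway(*groups.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(
        samples[value_col].to_numpy(dtype=float),
        samples[biome_col].to_numpy(),
        alpha=alpha,
    )
    names = list(tuk.groupsunique)
    different = {
        (names[i], names[j])
        for (i, j), rej in zip(
            ((i, j) for i in range(len(names)) for j in range(i + 1, len(names))),
            tuk.reject,
        )
        if rej
    }
    letters = _compact_letters(groups.keys(), different)
    summary["letters"] = summary["biome"].map(letters)
    return summary, float(anova_p)


def latitudinal_smooth(
    samples: pd.DataFrame,
    value_col: str = "ssci_pot",
    lat_col: str = "lat",
    df_spline: int = 10,
    n_grid: int = 200,
    seed: int = 0,
) -> dict:
    """Penalized-spline (GAM) smooth of SSCI_pot against latitude.

    Smoothness is chosen by generalized cross-validation (the search is
    seeded, so refits on the same data are identical).  Returns a dict with
    the evaluation grid, the fitted curve and a 95% confidence band.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    lat = samples[lat_col].to_numpy(dtype=float)
    y = samples[value_col].to_numpy(dtype=float)
    if lat.size < 20 or np.ptp(lat) < 10.0:
        raise ValueError("need >= 20 samples spanning >= 10 degrees latitude")
    grid0 = np.linspace(lat.min(), lat.max(), n_grid)
    if np.ptp(y) < 1e-12:
        flat = np.full(n_grid, y[0] if y.size else np.nan)
        return {"lat": grid0, "fit": flat, "lower": flat, "upper": flat,
                "alpha": np.inf}
    basis = BSplines(lat[:, None], df=[df_spline], degree=[3])
    gam = GLMGam(y, exog=np.ones((lat.size, 1)), smoother=basis)
    gam.fit()
    # the penalty search draws optimizer starts from the global RNG
    state = np.random.get_state()
    try:
        np.random.seed(seed)
        alpha = gam.select_penweight()[0]
    finally:
        np.random.set_state(state)
    res = GLMGam(y, exog=np.ones((lat.size, 1)), smoother=basis,
                 alpha=alpha).fit()
    grid = np.linspace(lat.min(), lat.max(), n_grid)
    exog_grid = np.column_stack([
        np.ones(n_grid), basis.transform(grid[:, None])
    ])
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    fit = exog_grid @ params
    se = np.sqrt(np.einsum("ij,jk,ik->i", exog_grid, cov, exog_grid))
    return {
        "lat": grid,
        "fit": fit,
        "lower": fit - 1.96 * se,
        "upper": fit + 1.96 * se,
        "alpha": alpha,
    }


def run_mapping(
    rasters: dict[str, Raster],
    ecoregion_features,
    model: PredictionModel,
    spacing_km: float = 50.0,
    envelope_mass: float = 0.95,
) -> tuple[pd.DataFrame, dict]:
    """The full sampling-to-prediction pipeline on user-supplied layers.

    Returns ``(samples, bookkeeping)`` where bookkeeping accounts exactly
    for every grid point: total = keyword_excluded + envelope_excluded +
    no_covariate + retained.
    """
    region = shapely.union_all([g for g, _ in ecoregion_features])
    grid = sample_grid(region=region, spacing_km=spacing_km)
    grid = assign_ecoregions(grid, ecoregion_features)
    total = len(grid)
    kept = ecoregion_keyword_filter(grid)
    keyword_excluded = total - len(kept)
    kept = kept.assign(
        MAP=rasters["MAP"].sample(kept["lon"].to_numpy(), kept["lat"].to_numpy()),
        prec_seasonality=rasters["prec_seasonality"].sample(
            kept["lon"].to_numpy(), kept["lat"].to_numpy()),
    )
    has_cov = kept[["MAP", "prec_seasonality"]].notna().all(axis=1)
    no_covariate = int((~has_cov).sum())
    kept = kept[has_cov].reset_index(drop=True)
    kept = envelope_filter_by_biome(kept, mass=envelope_mass)
    envelope_excluded = int((~kept["inside_envelope"]).sum())
    retained = kept[kept["inside_envelope"]].reset_index(drop=True)
    retained = predict_sscipot(retained, model)
    bookkeeping = {
        "total": total,
        "keyword_excluded": keyword_excluded,
        "no_covariate": no_covariate,
        "envelope_excluded": envelope_excluded,
        "retained": len(retained),
    }
    assert bookkeeping["total"] == sum(
        bookkeeping[k] for k in
        ("keyword_excluded", "no_covariate", "envelope_excluded", "retained")
    )
    return retained, bookkeeping
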