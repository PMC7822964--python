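"""Scan -> plot -> site aggregation and climate/soil covariate derivation.

Per-scan metrics are averaged to plot means; plot means are averaged to site
means with standard errors.  Climate covariates follow the usual
bioclimatic conventions: precipitation seasonality is the coefficient of
variation (%) of monthly rainfall; growing-season windows use the >= 5 degC
monthly-temperature rule in the temperate/boreal zone and the
P > 0.5 * PET rule in the tropics; soil variables for the standard depth
intervals are combined into a depth-weighted 1-m mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Standard soil depth intervals (cm) and their weights for a 1-m mean.
SOIL_DEPTH_INTERVALS = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100))
SOIL_DEPTH_WEIGHTS = np.array([5, 10, 15, 30, 40], dtype=float) / 100.0

#: Metric columns aggregated from scans to plots to sites.
METRIC_COLUMNS = ("ssci", "canopy_height", "basal_area", "canopy_openness")


def aggregate_scans_to_plots(scan_table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric over the scans of a plot.

    ``scan_table`` needs ``plot_id`` (and optionally ``site_id``) plus the
    metric columns; missing scans (NaN rows) are ignored per metric.
    """
    if "plot_id" not in scan_table:
        raise ValueError("scan table must have a 'plot_id' column")
    keys = [c for c in ("site_id", "plot_id") if c in scan_table]
    cols = [c for c in METRIC_COLUMNS if c in scan_table]
    out = scan_table.groupby(keys, sort=True)[cols].mean().reset_index()
    out["n_scans"] = scan_table.groupby(keys, sort=True).size().values
    return out


def aggregate_plots_to_sites(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Site mean and standard error of each metric over plot means.

    SE is the sample SD of plot means over sqrt(n_plots); a single-plot site
    reports SE 0 with ``se_defined = False``.
    """
    if "site_id" not in plot_table:
        raise ValueError("plot table must have a 'site_id' column")
    if len(plot_table) == 0:
        raise ValueError("no plots to aggregate")
    cols = [c for c in METRIC_COLUMNS if c in plot_table]
    rows = []
    for site_id, grp in plot_table.groupby("site_id", sort=True):
        n = len(grp)
        row: dict = {"site_id": site_id, "n_plots": n, "se_defined": n > 1}
        for c in cols:
            v = grp[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = float(np.mean(v))
            row[f"{c}_se"] = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MonthlyClimate:
    """Twelve monthly values of temperature (degC), precipitation (mm),
    PET (mm) and solar radiation (kJ m^-2 day^-1)."""

    temperature: np.ndarray
    precipitation: np.ndarray
    pet: np.ndarray | None = None
    solar_radiation: np.ndarray | None = None

    def __post_init__(self):
        for name in ("temperature", "precipitation", "pet", "solar_radiation"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (12,):
                raise ValueError(f"{name} must hold exactly 12 monthly values")
            setattr(self, name, v)


def growing_season_months(monthly: MonthlyClimate, zone: str) -> np.ndarray:
    """Indices (0-11) of growing-season months.

    ``temperate_boreal``: months with mean temperature >= 5 degC.
    ``tropical``: months with precipitation strictly above half the PET.
    """
    if zone == "temperate_boreal":
        return np.flatnonzero(monthly.temperature >= 5.0)
    if zone == "tropical":
        if monthly.pet is None:
            raise ValueError("tropical rule needs monthly PET")
        return np.flatnonzero(monthly.precipitation > 0.5 * monthly.pet)
    raise ValueError(f"unknown zone {zone!r}")


def growing_season_mean(series, months) -> float:
    """Arithmetic mean of a monthly series over the selected months."""
    months = np.asarray(months, dtype=int)
    if months.size == 0:
        raise ValueError("site has no growing season (empty month set)")
    series = np.asarray(series, dtype=float)
    if series.shape != (12,):
        raise ValueError("series must hold exactly 12 monthly values")
    return float(series[months].mean())


def precipitation_seasonality(monthly_precip) -> float:
    """Coefficient of variation (%) of monthly rainfall (population SD)."""
    p = np.asarray(monthly_precip, dtype=float)
    if p.shape != (12,):
        raise ValueError("need exactly 12 monthly precipitation values")
    m = p.mean()
    if m <= 0:
        raise ValueError("mean precipitation must be positive")
    return float(100.0 * p.std(ddof=0) / m)


def soil_depth_weighted_mean(values) -> float:
    """Depth-weighted 1-m mean over the five standard intervals
    (0-5, 5-15, 15-30, 30-60, 60-100 cm)."""
    v = np.asarray(values, dtype=float)
    if v.shape != (5,):
        raise ValueError("need one value per standard depth interval (5 values)")
    assert abs(SOIL_DEPTH_WEIGHTS.sum() - 1.0) < 1e-12
    return float(np.dot(SOIL_DEPTH_WEIGHTS, v))


def water_balance(map_mm: float, pet_mm: float) -> float:
    """Annual water balance: MAP - PET (mm)."""
    return float(map_mm - pet_mm)
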