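"""Small geodesic helpers shared by the sampling, modelling and synthetic
layers (spherical earth, radius 6371 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Kilometers per degree of latitude (and of longitude at the equator).
KM_PER_DEGREE = 111.32


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon, lat) points in degrees.

    Arguments broadcast like numpy arrays.
    """
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats) -> np.ndarray:
    """Symmetric matrix of great-circle distances (km) between points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
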