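"""Minimal georeferenced raster container with plain-text I/O.

Rasters are stored in geographic coordinates (lon/lat degrees) on a regular
grid and serialized as ESRI ASCII grids (``.asc``) — a text format readable
by GDAL, R and QGIS.  Values are printed with 17 significant digits so a
write/read round trip is bit-exact.  GeoJSON helpers cover the vector side
(ecoregion polygons) via shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape


@dataclass
class Raster:
    """A regular lon/lat grid; row 0 is the northernmost row."""

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def lon_centers(self) -> np.ndarray:
        ncols = self.data.shape[1]
        return self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 first (north to south)."""
        nrows = self.data.shape[0]
        top = self.yllcorner + nrows * self.cellsize
        return top - (np.arange(nrows) + 0.5) * self.cellsize

    def sample(self, lon, lat):
        """Nearest-pixel value at (lon, lat); NaN outside the grid or nodata."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        nrows, ncols = self.data.shape
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        top = self.yllcorner + nrows * self.cellsize
        row = np.floor((top - lat) / self.cellsize).astype(int)
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        out = np.full(np.broadcast(lon, lat).shape, np.nan)
        vals = self.data[row[inside], col[inside]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[inside] = vals
        return out if out.ndim else float(out)

    def write_ascii(self, path) -> None:
        nrows, ncols = self.data.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.xllcorner!r}\n")
            fh.write(f"yllcorner {self.yllcorner!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for row in self.data:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        header: dict[str, float] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value") and len(parts) == 2:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.array(rows, dtype=float)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data does not match its header")
        return cls(
            data=data,
            xllcorner=header["xllcorner"],
            yllcorner=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )


def write_geojson(features: list[tuple[object, dict]], path) -> None:
    """Write (shapely geometry, properties) pairs as a GeoJSON collection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": shapely_mapping(geom),
             "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_geojson(path) -> list[tuple[object, dict]]:
    """Read a GeoJSON collection into (shapely geometry, properties) pairs."""
    with open(path) as fh:
        collection = json.load(fh)
    return [
        (shapely_shape(f["geometry"]), f.get("properties", {}) or {})
        for f in collection["features"]
    ]
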