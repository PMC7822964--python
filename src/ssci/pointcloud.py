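"""Scan point clouds: containers, .xyz I/O, spherical transforms, thinning.

A single terrestrial laser scan is stored scanner-centered: the scanner sits
at the origin, z points up, and the ground plane of a flat scene lies at
z = -scanner_height (the instrument is mounted on a tripod ~1.3 m above
ground). All angular conventions are shared across the package:

* azimuth — degrees in [0, 360), measured counterclockwise from +x;
* elevation — degrees in [-90, 90], positive above the horizontal plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Tripod height of the scanner above local ground (m).
SCANNER_HEIGHT = 1.3

#: Native angular step of the instrument (degrees per step, per axis).
#: 360/10240 so that 1/16 resolution gives exactly 2560 azimuth columns.
NATIVE_ANGULAR_STEP = 360.0 / 10240.0


class XYZParseError(ValueError):
    """Raised when an .xyz file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class ScanConfig:
    """Angular sampling geometry of a scan.

    Parameters
    ----------
    vertical_fov : float
        Vertical field of view in degrees (default 300): the scan head sweeps
        through the zenith and down to ``90 - vertical_fov/2`` degrees
        elevation on every azimuth; the cone below the tripod is blind.
    horizontal_fov : float
        Horizontal field of view in degrees (default 360).
    angular_step : float
        Angular step between adjacent beams in degrees. The default is the
        post-export step (native step x 4 per axis, ~0.14 deg); pass
        ``NATIVE_ANGULAR_STEP`` to emulate the raw instrument grid.
    downsample_factor : int
        Resolution reduction applied on export: 1 point kept per ``factor``
        native points (a perfect square; decimation is ``sqrt(factor)`` per
        angular axis). 16 reproduces the standard export.
    """

    vertical_fov: float = 300.0
    horizontal_fov: float = 360.0
    angular_step: float = NATIVE_ANGULAR_STEP * 4
    downsample_factor: int = 16
    max_range: float = 120.0

    def __post_init__(self):
        if not (0 < self.angular_step):
            raise ValueError("angular_step must be positive")
        for name in ("vertical_fov", "horizontal_fov"):
            v = getattr(self, name)
            if not (0 < v <= 360):
                raise ValueError(f"{name} must be in (0, 360]")

    @property
    def elevation_min(self) -> float:
        return 90.0 - self.vertical_fov / 2.0

    @property
    def elevation_max(self) -> float:
        return 90.0

    def azimuths(self) -> np.ndarray:
        n = int(round(self.horizontal_fov / self.angular_step))
        return np.arange(n) * self.angular_step

    def elevations(self) -> np.ndarray:
        # never overshoot the zenith when the FOV is not a step multiple
        span = self.elevation_max - self.elevation_min
        n = int(np.floor(span / self.angular_step + 1e-9))
        return self.elevation_min + np.arange(n + 1) * self.angular_step


@dataclass
class PointCloud:
    """An ordered set of (x, y, z) returns of one scan, meters, scanner-centered."""

    xyz: np.ndarray
    scanner_height: float = SCANNER_HEIGHT

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


@dataclass
class SphericalPoints:
    """Scanner-centered spherical coordinates of a cloud (degrees, meters)."""

    azimuth: np.ndarray   # [0, 360), counterclockwise from +x
    elevation: np.ndarray  # [-90, 90], positive up
    range: np.ndarray      # > 0

    def __len__(self) -> int:
        return self.azimuth.shape[0]


def read_xyz(path) -> PointCloud:
    """Read a whitespace-separated 3-column ``.xyz`` text file.

    Lines starting with ``#`` and blank lines are ignored.  Malformed lines
    raise :class:`XYZParseError` naming the offending line number.
    """
    points = []
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise XYZParseError(
                    f"expected 3 columns, found {len(fields)}", line=lineno
                )
            try:
                points.append([float(v) for v in fields])
            except ValueError as exc:
                raise XYZParseError(str(exc), line=lineno) from None
            n_data += 1
    if n_data == 0:
        raise XYZParseError(f"no data lines in {path}")
    return PointCloud(np.array(points, dtype=float))


def write_xyz(cloud: PointCloud, path) -> None:
    """Write a cloud as whitespace-separated 3-column text (17 sig. digits)."""
    np.savetxt(path, cloud.xyz, fmt="%.17g")


def to_spherical(cloud: PointCloud) -> SphericalPoints:
    """Cartesian -> spherical (azimuth ccw from +x, elevation up, range)."""
    xyz = cloud.xyz
    r = np.linalg.norm(xyz, axis=1)
    if np.any(r == 0):
        raise ValueError("point at the scanner origin cannot be converted")
    az = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0])) % 360.0
    el = np.degrees(np.arcsin(np.clip(xyz[:, 2] / r, -1.0, 1.0)))
    return SphericalPoints(azimuth=az, elevation=el, range=r)


def from_spherical(sph: SphericalPoints) -> PointCloud:
    az = np.radians(sph.azimuth)
    el = np.radians(sph.elevation)
    r = sph.range
    cos_el = np.cos(el)
    xyz = np.column_stack((r * cos_el * np.cos(az), r * cos_el * np.sin(az), r * np.sin(el)))
    return PointCloud(xyz)


def downsample_angular(
    cloud: PointCloud,
    factor: int = 16,
    native_step: float = NATIVE_ANGULAR_STEP,
) -> PointCloud:
    """Thin a cloud to ``1/factor`` of its angular resolution.

    Returns are binned onto the native angular grid; within every coarse cell
    of ``sqrt(factor)`` native steps per axis the point closest to the cell's
    origin direction (smallest (azimuth offset, elevation offset), ties by
    input order) survives, so a cloud lying exactly on the native grid keeps
    every ``sqrt(factor)``-th azimuth and elevation index.
    """
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return PointCloud(cloud.xyz.copy(), cloud.scanner_height)
    s = math.isqrt(factor)
    if s * s != factor:
        raise ValueError("downsample factor must be a perfect square")
    sph = to_spherical(cloud)
    az_idx = np.round(sph.azimuth / native_step).astype(np.int64)
    el_idx = np.round((sph.elevation + 90.0) / native_step).astype(np.int64)
    cell = (az_idx // s) * (1 << 32) + (el_idx // s)
    # rank within a cell: lexicographic (az offset, el offset), then input order
    offset = (az_idx % s) * s + (el_idx % s)
    order = np.lexsort((np.arange(len(cloud)), offset, cell))
    keep_sorted = np.ones(len(cloud), dtype=bool)
    keep_sorted[1:] = cell[order][1:] != cell[order][:-1]
    keep = np.sort(order[keep_sorted])  # restore input order
    return PointCloud(cloud.xyz[keep], cloud.scanner_height)


def filter_stray(
    cloud: PointCloud,
    neighborhood_radius: float = 0.5,
    min_neighbors: int = 3,
) -> PointCloud:
    """Drop isolated returns: points with < ``min_neighbors`` other points
    within ``neighborhood_radius`` meters.

    A deterministic stand-in for the proprietary stray-point filters of the
    vendor software, which are not publicly specified.
    """
    if neighborhood_radius <= 0:
        raise ValueError("neighborhood_radius must be positive")
    if min_neighbors <= 0 or len(cloud) == 0:
        return PointCloud(cloud.xyz.copy(), cloud.scanner_height)
    tree = cKDTree(cloud.xyz)
    counts = tree.query_ball_point(cloud.xyz, r=neighborhood_radius, return_length=True)
    keep = (counts - 1) >= min_neighbors  # query counts the point itself
    if not np.any(keep):
        warnings.warn("stray filter removed every point", stacklevel=2)
    return PointCloud(cloud.xyz[keep], cloud.scanner_height)
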