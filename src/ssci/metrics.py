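"""Per-scan structural metrics.

The stand structural complexity index (SSCI) condenses one hemispherical
scan into a single number:

1. the cloud is split into opposite pairs of narrow azimuthal sectors and
   each pair's returns are chained into a closed cross-sectional polygon in
   the vertical cutting plane;
2. each polygon's shape complexity is scored with the fractal-dimension
   index ``FRAC = 2 ln(0.25 P) / ln A`` (perimeter P in m, area A in m^2),
   which is 1 for compact shapes and approaches 2 for highly convoluted
   outlines;
3. the mean FRAC over all valid polygons is scaled for vertical
   stratification: ``SSCI = MeanFRAC ** ln(ENL)`` where ENL, the effective
   number of layers, is the inverse Simpson index of the point counts in
   1-m height bins.

Canopy height (z extent), canopy openness (gap fraction of a zenith cone
after projecting return directions) and angle-count (Bitterlich) basal area
complete the per-scan record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pointcloud import PointCloud, ScanConfig, SphericalPoints, to_spherical

#: Sector width (degrees) giving 2560 azimuth sectors = 1280 opposite pairs.
DEFAULT_SECTOR_STEP = 360.0 / 2560.0


@dataclass
class CrossSectionPolygon:
    """Closed polygon in one vertical cutting plane.

    Vertices are (u, z): u is the signed horizontal distance from the
    scanner (positive in the first sector of the pair, negative in the
    opposite one) and z the height, both meters.
    """

    sector_pair_index: int
    vertices: np.ndarray  # (n, 2), closed implicitly (last connects to first)

    @property
    def perimeter(self) -> float:
        v = self.vertices
        d = np.diff(np.vstack([v, v[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def area(self) -> float:
        """Unsigned area by the shoelace rule on the closed vertex chain."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class ScanMetrics:
    """Structural metrics of one scan; ``ssci == mean_frac ** ln(enl)``."""

    mean_frac: float
    enl: float
    ssci: float
    canopy_height: float
    canopy_openness: float
    basal_area: float | None = None
    n_valid_polygons: int = 0
    n_skipped_polygons: int = 0

    def as_dict(self) -> dict:
        return {
            "mean_frac": self.mean_frac,
            "enl": self.enl,
            "ssci": self.ssci,
            "canopy_height": self.canopy_height,
            "canopy_openness": self.canopy_openness,
            "basal_area": self.basal_area,
            "n_valid_polygons": self.n_valid_polygons,
            "n_skipped_polygons": self.n_skipped_polygons,
        }


def build_cross_sections(
    sph: SphericalPoints,
    angular_step: float = DEFAULT_SECTOR_STEP,
) -> tuple[list[CrossSectionPolygon], int]:
    """Chain each pair of opposite azimuthal sectors into a closed polygon.

    Sector k (azimuth band ``[k*step, (k+1)*step)``) is paired with sector
    k + n/2.  Along side A the returns are ordered by ascending elevation
    (horizon up to the zenith), side B follows in descending elevation, and
    the chain closes from the last vertex back to the first.  Pairs holding
    fewer than 3 returns in total are skipped.

    Returns ``(polygons, n_skipped)``.
    """
    if len(sph) == 0:
        raise ValueError("cannot build cross-sections from an empty cloud")
    n_sectors = int(round(360.0 / angular_step))
    if n_sectors % 2 or not math.isclose(n_sectors * angular_step, 360.0):
        raise ValueError("angular_step must divide 360 into an even sector count")
    half = n_sectors // 2

    # nudge guards against returns lying exactly on a sector boundary
    sector = np.floor(sph.azimuth / angular_step + 1e-9).astype(np.int64)
    sector = np.minimum(sector, n_sectors - 1)
    pair = np.where(sector >= half, sector - half, sector)
    side_b = sector >= half
    u = sph.range * np.cos(np.radians(sph.elevation))
    z = sph.range * np.sin(np.radians(sph.elevation))

    order = np.lexsort((sph.elevation, pair))
    pair_s, side_s = pair[order], side_b[order]
    u_s, z_s, el_s = u[order], z[order], sph.elevation[order]

    polygons: list[CrossSectionPolygon] = []
    n_skipped = 0
    boundaries = np.flatnonzero(np.diff(pair_s)) + 1
    for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(pair_s)]):
        k = int(pair_s[lo])
        if hi - lo < 3:
            n_skipped += 1
            continue
        a = slice(lo, hi)
        on_b = side_s[a]
        # side A ascending elevation, then side B descending elevation
        ua = u_s[a][~on_b]
        za = z_s[a][~on_b]
        ub = -u_s[a][on_b][::-1]
        zb = z_s[a][on_b][::-1]
        verts = np.column_stack((np.r_[ua, ub], np.r_[za, zb]))
        polygons.append(CrossSectionPolygon(sector_pair_index=k, vertices=verts))
    return polygons, n_skipped


def frac_dimension(polygon: CrossSectionPolygon) -> float | None:
    """Fractal-dimension index ``2 ln(0.25 P) / ln A``, clipped to [1, 2].

    Polygons with area <= 1 m^2 or perimeter <= 4 m leave the index
    ill-defined and return ``None`` (excluded from MeanFRAC).
    """
    P = polygon.perimeter
    A = polygon.area
    if A <= 1.0 or P <= 4.0:
        return None
    return float(np.clip(2.0 * math.log(0.25 * P) / math.log(A), 1.0, 2.0))


def effective_layers(cloud: PointCloud, bin_width: float = 1.0) -> float:
    """Effective number of layers: inverse Simpson index of the point counts
    in ``bin_width``-m height bins anchored at ``floor(min z)``."""
    if len(cloud) == 0:
        raise ValueError("cannot compute ENL of an empty cloud")
    z = cloud.z
    idx = np.floor((z - np.floor(z.min())) / bin_width).astype(np.int64)
    counts = np.bincount(idx).astype(float)
    p = counts / counts.sum()
    return float(1.0 / np.sum(p * p))


def ssci(mean_frac: float, enl: float) -> float:
    """``SSCI = MeanFRAC ** ln(ENL)``: shape complexity of the cross-section
    polygons scaled by the (log) effective vertical stratification."""
    if not (1.0 <= mean_frac <= 2.0):
        raise ValueError("mean_frac must lie in [1, 2]")
    if enl < 1.0:
        raise ValueError("enl must be >= 1")
    return float(mean_frac ** math.log(enl))


def canopy_height(cloud: PointCloud) -> float:
    """Vertical extent of the scan: max z minus min z."""
    if len(cloud) == 0:
        raise ValueError("cannot compute canopy height of an empty cloud")
    return float(cloud.z.max() - cloud.z.min())


def canopy_openness(
    sph: SphericalPoints,
    opening_angle: float = 60.0,
    grid_resolution: float = 1.0,
) -> float:
    """Gap fraction of the zenith cone with full apex angle ``opening_angle``.

    Return directions are binned into equal-solid-angle cells (uniform in
    azimuth x cos(zenith), cells about ``grid_resolution`` degrees across at
    the cone rim); openness is the fraction of cells without any return.
    """
    if not (0 < opening_angle < 180):
        raise ValueError("opening_angle must be in (0, 180)")
    zen_max = math.radians(opening_angle / 2.0)
    n_az = max(1, int(round(360.0 / grid_resolution)))
    n_mu = max(1, int(round(math.degrees(zen_max) / grid_resolution)))
    mu_lo = math.cos(zen_max)

    zen = np.radians(90.0 - sph.elevation)
    in_cone = zen <= zen_max
    total = n_az * n_mu
    if total == 0:
        raise ValueError("no cells inside the opening cone")
    if not np.any(in_cone):
        return 1.0
    az_i = np.minimum((sph.azimuth[in_cone] / (360.0 / n_az)).astype(np.int64),
                      n_az - 1)
    mu = np.cos(zen[in_cone])
    mu_i = np.minimum(((mu - mu_lo) / ((1.0 - mu_lo) / n_mu)).astype(np.int64),
                      n_mu - 1)
    occupied = np.unique(az_i * n_mu + mu_i).size
    return float(1.0 - occupied / total)


def basal_area_angle_count(
    trees_visible: list[tuple[float, float]],
    basal_area_factor: float = 2.0,
) -> float:
    """Bitterlich angle-count estimate of stand basal area (m^2/ha).

    ``trees_visible`` holds ``(dbh_m, distance_m)`` for candidate stems; a
    stem is tallied when its diameter subtends at least the critical angle,
    i.e. ``distance <= dbh * 50 / sqrt(BAF)``; estimate = BAF x tally.
    """
    if basal_area_factor <= 0:
        raise ValueError("basal_area_factor must be positive")
    count = 0
    for dbh, dist in trees_visible:
        if dbh <= 0 or dist <= 0:
            raise ValueError("dbh and distance must be positive")
        if dist <= dbh * 50.0 / math.sqrt(basal_area_factor):
            count += 1
    return basal_area_factor * count


def basal_area_from_scene(scene, scanner_xy, basal_area_factor: float = 2.0) -> float:
    """Angle-count basal area sampled from a synthetic scene at a position."""
    sx, sy = scanner_xy
    pairs = [
        (t.stem_diameter_breast_height, math.hypot(t.x - sx, t.y - sy))
        for t in scene.trees
        if t.stem_height > 0 and math.hypot(t.x - sx, t.y - sy) > 0
    ]
    return basal_area_angle_count(pairs, basal_area_factor)


def compute_scan_metrics(
    cloud: PointCloud,
    config: ScanConfig | None = None,
    opening_angle: float = 60.0,
    basal_area: float | None = None,
) -> ScanMetrics:
    """Full per-scan metric record from a (filtered, downsampled) cloud."""
    config = config or ScanConfig()
    sph = to_spherical(cloud)
    polygons, n_skipped = build_cross_sections(sph, angular_step=config.angular_step)
    fracs = [f for f in (frac_dimension(p) for p in polygons) if f is not None]
    n_invalid = len(polygons) - len(fracs)
    if not fracs:
        raise ValueError("no valid cross-sectional polygon in the scan")
    mean_frac = float(np.mean(fracs))
    enl = effective_layers(cloud)
    return ScanMetrics(
        mean_frac=mean_frac,
        enl=enl,
        ssci=ssci(mean_frac, enl),
        canopy_height=canopy_height(cloud),
        canopy_openness=canopy_openness(sph, opening_angle=opening_angle),
        basal_area=basal_area,
        n_valid_polygons=len(fracs),
        n_skipped_polygons=n_skipped + n_invalid,
    )
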