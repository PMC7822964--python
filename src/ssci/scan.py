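"""Simulated terrestrial laser scans of synthetic scenes by ray casting.

One beam is cast per (azimuth, elevation) cell of the configured angular
grid.  Each beam returns the first surface it meets: flat ground, an opaque
stem cylinder, or a crown shell (accepted with the crown's surface
probability, otherwise the beam passes through that crown entirely).  Beams
that meet nothing within the instrument range produce no return (open sky).
Returned coordinates are scanner-centered with the scanner 1.3 m above local
ground, matching the convention of :mod:`ssci.pointcloud`.
"""

from __future__ import annotations

import numpy as np

from .forest import Scene, Tree
from .pointcloud import SCANNER_HEIGHT, PointCloud, ScanConfig

_EPS = 1e-9
_INF = np.inf


def _quad_min_positive(A, B, C, z_lo, z_hi, dz):
    """Smallest t > 0 solving A t^2 + B t + C = 0 with t*dz in [z_lo, z_hi].

    Arrays broadcast; cells with no valid root get +inf.  Degenerate (A ~ 0)
    cells are solved linearly.
    """
    A, B, C, dz = np.broadcast_arrays(
        np.asarray(A, dtype=float), B, C, dz
    )
    out = np.full(A.shape, _INF)
    lin = np.abs(A) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - 4.0 * A * C
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        t1 = (-B - sq) / (2.0 * A)
        t2 = (-B + sq) / (2.0 * A)
        tl = np.where(np.abs(B) > 1e-14, -C / B, np.nan)
    for t, mask in ((t1, ~lin), (t2, ~lin), (tl, lin)):
        band = t * dz
        valid = mask & np.isfinite(t) & (t > _EPS)
        valid &= (band >= z_lo) & (band <= z_hi)
        out = np.where(valid & (t < out), t, out)
    return out


def _disc_hit(z_cap, radius, cx, cy, dx, dy, dz):
    """t of a horizontal disc at height z_cap, center (cx, cy), or +inf."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = z_cap / dz
        px = t * dx - cx
        py = t * dy - cy
        inside = px * px + py * py <= radius * radius
    ok = np.isfinite(t) & (t > _EPS) & inside
    return np.where(ok, t, _INF)


def _crown_t(tree: Tree, cx, cy, z0, dx, dy, dz):
    """First crossing of the crown shell of ``tree`` (centered at cx, cy in
    the scanner frame, ground at z0), or +inf per beam."""
    zb = tree.crown_base + z0
    zt = tree.crown_top + z0
    R = tree.crown_radius
    if tree.crown_shape == "ellipsoid":
        cz = 0.5 * (zb + zt)
        av = 0.5 * (zt - zb)
        A = (dx * dx + dy * dy) / (R * R) + (dz * dz) / (av * av)
        B = -2.0 * ((cx * dx + cy * dy) / (R * R) + cz * dz / (av * av))
        C = (cx * cx + cy * cy) / (R * R) + (cz * cz) / (av * av) - 1.0
        return _quad_min_positive(A, B, C, -_INF, _INF, dz)
    if tree.crown_shape == "cone":
        # apex at crown top; radius R at the crown base
        k = R / (zt - zb)
        A = dx * dx + dy * dy - k * k * dz * dz
        B = -2.0 * (cx * dx + cy * dy) + 2.0 * k * k * zt * dz
        C = cx * cx + cy * cy - k * k * zt * zt
        lateral = _quad_min_positive(A, B, C, zb, zt, dz)
        base = _disc_hit(zb, R, cx, cy, dx, dy, dz)
        return np.minimum(lateral, base)
    if tree.crown_shape == "cylinder":
        A = dx * dx + dy * dy
        B = -2.0 * (cx * dx + cy * dy)
        C = cx * cx + cy * cy - R * R
        lateral = _quad_min_positive(A, B, C, zb, zt, dz)
        caps = np.minimum(
            _disc_hit(zb, R, cx, cy, dx, dy, dz),
            _disc_hit(zt, R, cx, cy, dx, dy, dz),
        )
        return np.minimum(lateral, caps)
    raise ValueError(f"unknown crown shape {tree.crown_shape!r}")


def _stem_t(tree: Tree, cx, cy, z0, dx, dy, dz):
    """Nearest-wall hit on the opaque stem cylinder, or +inf per beam."""
    r = tree.stem_diameter_breast_height / 2.0
    A = dx * dx + dy * dy
    B = -2.0 * (cx * dx + cy * dy)
    C = cx * cx + cy * cy - r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - 4.0 * A * C
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        t1 = (-B - sq) / (2.0 * A)   # near wall only; the top cap is ignored
    band = t1 * dz
    ok = np.isfinite(t1) & (t1 > _EPS) & (band >= z0) & (band <= z0 + tree.stem_height)
    return np.where(ok, t1, _INF)


def clear_scanner_position(
    scene: Scene,
    preferred: tuple[float, float] = (0.0, 0.0),
    clearance: float = 0.3,
    search_step: float = 0.5,
    max_radius: float = 10.0,
) -> tuple[float, float]:
    """Nearest tripod spot to ``preferred`` with ``clearance`` meters of free
    space around every stem (a field crew shifts the tripod rather than set
    it up against a trunk).  Searches outward on a ring pattern."""
    px, py = preferred
    stems = [(t.x, t.y, t.stem_diameter_breast_height / 2.0)
             for t in scene.trees if t.stem_height > 0]
    xmin, ymin, xmax, ymax = scene.extent

    def clear(x, y):
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            return False
        return all(np.hypot(x - sx, y - sy) - r >= clearance
                   for sx, sy, r in stems)

    if clear(px, py):
        return (px, py)
    r = search_step
    while r <= max_radius:
        for ang in np.linspace(0.0, 2.0 * np.pi, max(8, int(8 * r)),
                               endpoint=False):
            x, y = px + r * np.cos(ang), py + r * np.sin(ang)
            if clear(x, y):
                return (float(x), float(y))
        r += search_step
    raise ValueError("no clear scanner position within the search radius")


def simulate_scan(
    scene: Scene,
    scanner_xy: tuple[float, float],
    config: ScanConfig | None = None,
    seed: int = 0,
) -> PointCloud:
    """Ray-cast one scan of ``scene`` from ``scanner_xy``.

    Deterministic for a given ``(scene, scanner_xy, config, seed)``; the seed
    drives only the probabilistic crown-surface interception.
    """
    config = config or ScanConfig()
    sx, sy = scanner_xy
    xmin, ymin, xmax, ymax = scene.extent
    if not (xmin <= sx <= xmax and ymin <= sy <= ymax):
        raise ValueError("scanner position lies outside the scene extent")
    for tree in scene.trees:
        if tree.stem_height > 0 and np.hypot(tree.x - sx, tree.y - sy) <= \
                tree.stem_diameter_breast_height / 2.0:
            raise ValueError("scanner placed inside a stem")

    az = np.radians(config.azimuths())
    el = np.radians(config.elevations())
    cos_az, sin_az = np.cos(az), np.sin(az)
    cos_el, sin_el = np.cos(el), np.sin(el)
    n_az, n_el = az.size, el.size
    step = config.angular_step

    best_t = np.full((n_az, n_el), _INF)

    # flat ground at z = -scanner_height in the scanner frame
    z0 = -SCANNER_HEIGHT
    down = sin_el < -_EPS
    with np.errstate(divide="ignore"):
        t_ground = np.where(down, z0 / sin_el, _INF)
    best_t[:] = t_ground[None, :]

    rng = np.random.default_rng(seed)
    az_deg = config.azimuths()
    for tree in scene.trees:
        cx, cy = tree.x - sx, tree.y - sy
        dist = np.hypot(cx, cy)
        r_occ = max(tree.crown_radius, tree.stem_diameter_breast_height / 2.0)
        if dist > r_occ + _EPS:
            half = np.degrees(np.arcsin(min(1.0, r_occ / dist)))
            az_c = np.degrees(np.arctan2(cy, cx)) % 360.0
            diff = (az_deg - az_c + 180.0) % 360.0 - 180.0
            cols = np.nonzero(np.abs(diff) <= half + step)[0]
        else:
            cols = np.arange(n_az)
        if cols.size == 0:
            continue
        dx = cos_az[cols][:, None] * cos_el[None, :]
        dy = sin_az[cols][:, None] * cos_el[None, :]
        dz = np.broadcast_to(sin_el[None, :], (cols.size, n_el))
        t_tree = np.full((cols.size, n_el), _INF)
        if tree.stem_height > 0:
            t_tree = np.minimum(t_tree, _stem_t(tree, cx, cy, z0, dx, dy, dz))
        if tree.crown_point_density > 0:
            t_crown = _crown_t(tree, cx, cy, z0, dx, dy, dz)
            if tree.crown_point_density < 1.0:
                accept = rng.random((cols.size, n_el)) < tree.crown_point_density
                t_crown = np.where(accept, t_crown, _INF)
            t_tree = np.minimum(t_tree, t_crown)
        best_t[cols] = np.minimum(best_t[cols], t_tree)

    hit = best_t <= config.max_range
    ia, ie = np.nonzero(hit)
    t = best_t[ia, ie]
    xyz = np.column_stack((
        t * cos_az[ia] * cos_el[ie],
        t * sin_az[ia] * cos_el[ie],
        t * sin_el[ie],
    ))
    return PointCloud(xyz)
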