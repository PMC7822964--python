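"""Synthetic forest stands: trees with parametric crowns, layered scenes,
and the five-on-a-dice scan layout.

Scenes are built in world coordinates (ground at ``ground_elevation``, z up).
Crowns are geometric shells (ellipsoid, cone or cylinder) that intercept a
laser beam with a fixed surface probability; this spans open to closed
canopies with a single knob and stands in for foliage, which is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

CrownShape = Literal["ellipsoid", "cone", "cylinder"]


class EmptySceneError(ValueError):
    """Raised when a scene with trees was requested but none could be placed."""


@dataclass
class Tree:
    """One stem plus a parametric crown shell.

    All lengths in meters.  ``crown_point_density`` is the probability that a
    beam crossing the crown surface produces a return there (otherwise the
    beam continues); the stem is always opaque.  ``stem_height = 0`` means no
    stem (used for abstract occluders in tests).
    """

    x: float
    y: float
    stem_height: float
    stem_diameter_breast_height: float
    crown_base: float
    crown_top: float
    crown_radius: float
    crown_shape: CrownShape = "ellipsoid"
    crown_point_density: float = 0.3

    def __post_init__(self):
        if not (self.crown_top > self.crown_base >= 0):
            raise ValueError("need crown_top > crown_base >= 0")
        if self.stem_diameter_breast_height <= 0:
            raise ValueError("stem_diameter_breast_height must be positive")
        if self.crown_radius <= 0:
            raise ValueError("crown_radius must be positive")
        if not (0 <= self.crown_point_density <= 1):
            raise ValueError("crown_point_density must be in [0, 1]")

    @property
    def basal_area(self) -> float:
        """Stem cross-section at breast height (m^2)."""
        return np.pi * (self.stem_diameter_breast_height / 2.0) ** 2


@dataclass
class StratumSpec:
    """One vertical canopy layer to populate with trees.

    ``height_band`` bounds every crown in the stratum: crown_base and
    crown_top are drawn inside it (base in the lower half, top in the upper
    half, so crowns always have positive depth).
    """

    height_band: tuple[float, float]
    density: float                              # stems per hectare
    crown_radius_range: tuple[float, float] = (2.0, 4.0)
    dbh_range: tuple[float, float] | None = None  # default: scaled to height
    crown_shape: CrownShape = "ellipsoid"
    crown_point_density: float = 0.3

    def __post_init__(self):
        lo, hi = self.height_band
        if not (hi > lo >= 0):
            raise ValueError("height_band must satisfy hi > lo >= 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass
class SceneSpec:
    """Recipe for a layered stand on a rectangular extent (meters)."""

    strata: Sequence[StratumSpec]
    extent: tuple[float, float, float, float] = (-50.0, -50.0, 50.0, 50.0)
    ground_elevation: float = 0.0


@dataclass
class Scene:
    trees: list[Tree]
    extent: tuple[float, float, float, float]
    ground_elevation: float = 0.0
    strata_spec: SceneSpec | None = None

    @property
    def area_ha(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin) / 1e4

    def true_basal_area(self) -> float:
        """Stand basal area (m^2 / ha) from the stems actually placed."""
        return sum(t.basal_area for t in self.trees if t.stem_height > 0) / self.area_ha


def make_scene(spec: SceneSpec, seed: int) -> Scene:
    """Populate a scene deterministically from ``(spec, seed)``.

    Each stratum receives ``round(density * area_ha)`` trees at uniform
    positions.  Raises :class:`EmptySceneError` when a positive density was
    requested but the extent is too small to hold a single tree.
    """
    xmin, ymin, xmax, ymax = spec.extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("scene extent is degenerate")
    rng = np.random.default_rng(seed)
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    trees: list[Tree] = []
    requested = 0.0
    for stratum in spec.strata:
        requested += stratum.density
        n = int(round(stratum.density * area_ha))
        if n == 0:
            continue
        lo, hi = stratum.height_band
        mid = 0.5 * (lo + hi)
        xs = rng.uniform(xmin, xmax, n)
        ys = rng.uniform(ymin, ymax, n)
        bases = rng.uniform(lo, mid, n)
        tops = rng.uniform(mid, hi, n)
        radii = rng.uniform(*stratum.crown_radius_range, n)
        if stratum.dbh_range is not None:
            dbhs = rng.uniform(*stratum.dbh_range, n)
        else:
            dbhs = 0.02 * tops  # crude allometry: dbh ~ 2 cm per m of height
        for i in range(n):
            trees.append(
                Tree(
                    x=float(xs[i]),
                    y=float(ys[i]),
                    stem_height=float(tops[i]),
                    stem_diameter_breast_height=float(dbhs[i]),
                    crown_base=float(bases[i]),
                    crown_top=float(tops[i]),
                    crown_radius=float(radii[i]),
                    crown_shape=stratum.crown_shape,
                    crown_point_density=stratum.crown_point_density,
                )
            )
    if requested > 0 and not trees:
        raise EmptySceneError(
            "positive stem density requested but the extent holds no tree"
        )
    return Scene(trees=trees, extent=spec.extent,
                 ground_elevation=spec.ground_elevation, strata_spec=spec)


def multilayer_scene_spec(
    extent: tuple[float, float, float, float] = (-30.0, -30.0, 30.0, 30.0),
) -> SceneSpec:
    """Canonical three-layered stand: shrub understory (2-5 m), mid-story
    (10-15 m) and overstory (25-30 m), with crown radii scaled to each
    layer's stature."""
    return SceneSpec(
        strata=[
            StratumSpec((2.0, 5.0), 300.0, crown_radius_range=(0.8, 1.5)),
            StratumSpec((10.0, 15.0), 150.0, crown_radius_range=(1.5, 2.5)),
            StratumSpec((25.0, 30.0), 150.0, crown_radius_range=(2.5, 4.0)),
        ],
        extent=extent,
    )


def single_layer_scene_spec(
    extent: tuple[float, float, float, float] = (-30.0, -30.0, 30.0, 30.0),
) -> SceneSpec:
    """Canonical single-layered stand: one 25-30 m overstory at the same
    total stature as the layered stand's top layer."""
    return SceneSpec(
        strata=[StratumSpec((25.0, 30.0), 300.0, crown_radius_range=(2.5, 4.0))],
        extent=extent,
    )


def place_plot_scans(
    plot_center: tuple[float, float],
    offset: float = 42.0,
) -> list[tuple[float, float]]:
    """Five-on-a-dice scan layout on a 100 x 100 m plot: the plot center plus
    four positions ``offset`` meters from it toward the plot corners."""
    cx, cy = plot_center
    d = offset / np.sqrt(2.0)
    return [
        (cx, cy),
        (cx + d, cy + d),
        (cx - d, cy + d),
        (cx - d, cy - d),
        (cx + d, cy - d),
    ]
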