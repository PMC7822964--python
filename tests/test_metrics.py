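import math

import numpy as np
import pytest

from ssci import (
    CrossSectionPolygon,
    PointCloud,
    ScanConfig,
    Scene,
    SceneSpec,
    SphericalPoints,
    StratumSpec,
    Tree,
    basal_area_angle_count,
    basal_area_from_scene,
    build_cross_sections,
    canopy_height,
    canopy_openness,
    compute_scan_metrics,
    effective_layers,
    frac_dimension,
    make_scene,
    simulate_scan,
    ssci,
    to_spherical,
)
from ssci.metrics import DEFAULT_SECTOR_STEP
from ssci.pointcloud import SCANNER_HEIGHT


def _square(side, x0=0.0, z0=0.0):
    v = np.array([[x0, z0], [x0 + side, z0], [x0 + side, z0 + side],
                  [x0, z0 + side]])
    return CrossSectionPolygon(sector_pair_index=0, vertices=v)


def _cylindrical_room(width=10.0, height=10.0):
    """Closed cylindrical room around the scanner: cross-sections are
    width x height rectangles."""
    room = Tree(x=0, y=0, stem_height=0, stem_diameter_breast_height=0.01,
                crown_base=1e-4, crown_top=height - SCANNER_HEIGHT,
                crown_radius=width / 2, crown_shape="cylinder",
                crown_point_density=1.0)
    return Scene(trees=[room], extent=(-50, -50, 50, 50))


class TestCrossSections:
    def test_reduced_step_yields_1280_pairs(self):
        cloud = simulate_scan(Scene(trees=[], extent=(-50, -50, 50, 50)),
                              (0, 0), ScanConfig())
        polygons, skipped = build_cross_sections(
            to_spherical(cloud), DEFAULT_SECTOR_STEP
        )
        assert len(polygons) == 1280

    def test_room_polygons_are_near_square(self):
        cfg = ScanConfig(angular_step=0.5)
        cloud = simulate_scan(_cylindrical_room(), (0, 0), cfg)
        polygons, _ = build_cross_sections(to_spherical(cloud), 0.5)
        fracs = [frac_dimension(p) for p in polygons]
        assert all(f is not None for f in fracs)
        assert max(abs(f - 1.0) for f in fracs) < 0.02

    def test_pair_with_two_points_is_skipped(self):
        sph = SphericalPoints(
            azimuth=np.array([0.05, 180.05, 90.11, 90.13, 90.15, 270.11]),
            elevation=np.array([10.0, 20.0, 5.0, 15.0, 25.0, 30.0]),
            range=np.full(6, 8.0),
        )
        polygons, skipped = build_cross_sections(sph, angular_step=0.1)
        assert skipped == 1          # the 0/180 pair holds only 2 points
        assert len(polygons) == 1    # the 90/270 pair survives with 4 points

    def test_empty_input_rejected(self):
        sph = SphericalPoints(np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            build_cross_sections(sph)

    def test_odd_sector_count_rejected(self):
        sph = SphericalPoints(np.array([0.0]), np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            build_cross_sections(sph, angular_step=360.0 / 2561)


class TestFracDimension:
    @pytest.mark.parametrize("side", [10.0, 100.0, 2.0, 55.5])
    def test_square_identity(self, side):
        assert frac_dimension(_square(side)) == pytest.approx(1.0, abs=1e-12)

    def test_sawtooth_matches_independent_geometry_oracle(self):
        # jagged-top rectangle built programmatically
        rng = np.random.default_rng(4)
        xs = np.linspace(0, 20, 41)
        top = 10 + rng.uniform(-1, 1, xs.size)
        verts = np.vstack([
            np.column_stack([xs, np.zeros(xs.size)]),
            np.column_stack([xs[::-1], top[::-1]]),
        ])
        poly = CrossSectionPolygon(0, verts)
        # independent shoelace + arc-length re-implementation
        closed = np.vstack([verts, verts[:1]])
        per = sum(math.dist(closed[i], closed[i + 1])
                  for i in range(len(verts)))
        area = 0.5 * abs(sum(
            closed[i][0] * closed[i + 1][1] - closed[i + 1][0] * closed[i][1]
            for i in range(len(verts))
        ))
        expected = min(2.0, max(1.0, 2 * math.log(0.25 * per) / math.log(area)))
        assert frac_dimension(poly) == pytest.approx(expected, abs=1e-12)
        assert frac_dimension(poly) > 1.0

    def test_small_area_marks_invalid(self):
        assert frac_dimension(_square(0.9)) is None

    def test_simulated_scan_polygons_within_bounds(self, overstory_metrics):
        assert 1.0 <= overstory_metrics.mean_frac <= 2.0


class TestEffectiveLayers:
    def test_single_layer(self):
        z = np.full(50, 3.2)
        cloud = PointCloud(np.column_stack([np.arange(50), np.arange(50), z]))
        assert effective_layers(cloud) == pytest.approx(1.0)

    def test_uniform_four_layers(self):
        z = np.repeat([0.5, 1.5, 2.5, 3.5], 25)
        cloud = PointCloud(np.column_stack([np.ones(100), np.ones(100), z]))
        assert effective_layers(cloud) == pytest.approx(4.0)

    def test_75_25_split(self):
        z = np.r_[np.full(75, 0.5), np.full(25, 1.5)]
        cloud = PointCloud(np.column_stack([np.ones(100), np.ones(100), z]))
        assert effective_layers(cloud) == pytest.approx(1.6)

    def test_concentration_reduces_enl(self):
        z_even = np.repeat([0.5, 1.5, 2.5, 3.5], 25)
        z_skew = np.r_[np.full(85, 0.5), np.full(5, 1.5), np.full(5, 2.5),
                       np.full(5, 3.5)]
        mk = lambda z: PointCloud(np.column_stack([np.ones(z.size)] * 2 + [z]))
        assert effective_layers(mk(z_skew)) < effective_layers(mk(z_even))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_layers(PointCloud(np.empty((0, 3))))


class TestSSCI:
    def test_enl_one_gives_one(self):
        for mf in (1.0, 1.3, 1.999):
            assert ssci(mf, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_enl_e_returns_mean_frac(self):
        assert ssci(1.4, math.e) == pytest.approx(1.4, abs=1e-12)

    def test_direct_evaluation(self):
        assert ssci(1.5, 20.0) == pytest.approx(1.5 ** math.log(20.0))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ssci(0.9, 2.0)
        with pytest.raises(ValueError):
            ssci(1.5, 0.5)

    def test_monotone_in_both_arguments(self):
        assert ssci(1.6, 5.0) > ssci(1.5, 5.0)
        assert ssci(1.5, 6.0) > ssci(1.5, 5.0)


class TestCanopyHeightAndOpenness:
    def test_ground_only_height_near_zero(self):
        cloud = simulate_scan(Scene(trees=[], extent=(-50, -50, 50, 50)),
                              (0, 0), ScanConfig(angular_step=1.0))
        assert canopy_height(cloud) == pytest.approx(0.0, abs=1e-6)

    def test_slab_scene_height(self):
        base = 10.0 + SCANNER_HEIGHT
        slab = Tree(x=0, y=0, stem_height=0, stem_diameter_breast_height=0.01,
                    crown_base=base, crown_top=base + 0.01, crown_radius=500,
                    crown_shape="cylinder", crown_point_density=1.0)
        cloud = simulate_scan(Scene(trees=[slab], extent=(-50, -50, 50, 50)),
                              (0, 0), ScanConfig(angular_step=1.0))
        assert canopy_height(cloud) == pytest.approx(10.0 + SCANNER_HEIGHT,
                                                     abs=0.05)

    def test_single_point_height_zero(self):
        assert canopy_height(PointCloud([[1.0, 2.0, 3.0]])) == 0.0

    def test_open_sky(self):
        sph = SphericalPoints(azimuth=np.array([10.0]),
                              elevation=np.array([-45.0]),
                              range=np.array([2.0]))
        assert canopy_openness(sph) == 1.0

    def test_closed_canopy(self):
        # returns everywhere inside the 30-degree zenith cone
        az, zen = np.meshgrid(np.arange(0, 360, 0.5), np.arange(0, 30, 0.25))
        sph = SphericalPoints(azimuth=az.ravel(),
                              elevation=90.0 - zen.ravel(),
                              range=np.full(az.size, 10.0))
        assert canopy_openness(sph) == 0.0

    def test_half_covered_cone(self):
        az, zen = np.meshgrid(np.arange(0, 180, 0.25), np.arange(0, 30, 0.25))
        sph = SphericalPoints(azimuth=az.ravel(),
                              elevation=90.0 - zen.ravel(),
                              range=np.full(az.size, 10.0))
        assert canopy_openness(sph) == pytest.approx(0.5, abs=0.02)

    def test_openness_antitone_in_cover(self):
        def cov(frac):
            az, zen = np.meshgrid(np.arange(0, 360 * frac, 0.25),
                                  np.arange(0, 30, 0.25))
            return canopy_openness(SphericalPoints(
                azimuth=az.ravel(), elevation=90.0 - zen.ravel(),
                range=np.full(az.size, 10.0)))
        vals = [cov(f) for f in (0.2, 0.5, 0.8)]
        assert vals[0] > vals[1] > vals[2]


class TestBasalArea:
    def test_no_trees(self):
        assert basal_area_angle_count([], 2.0) == 0.0

    def test_estimator_arithmetic(self):
        # 13 stems inside the critical distance, BAF 2 -> 26 m2/ha
        trees = [(0.4, 10.0)] * 13 + [(0.2, 30.0)] * 5
        assert basal_area_angle_count(trees, 2.0) == pytest.approx(26.0)

    def test_critical_distance_boundary(self):
        crit = 0.4 * 50 / math.sqrt(2.0)
        assert basal_area_angle_count([(0.4, crit)], 2.0) == 2.0
        assert basal_area_angle_count([(0.4, crit + 1e-9)], 2.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            basal_area_angle_count([(0.0, 5.0)], 2.0)
        with pytest.raises(ValueError):
            basal_area_angle_count([(0.4, 5.0)], 0.0)

    def test_monte_carlo_unbiasedness(self):
        spec = SceneSpec(
            strata=[StratumSpec((20, 30), 300.0, dbh_range=(0.2, 0.6))],
            extent=(-200, -200, 200, 200),
        )
        scene = make_scene(spec, seed=11)
        truth = scene.true_basal_area()
        rng = np.random.default_rng(12)
        # sample well inside so no inclusion circle leaves the stand
        xs = rng.uniform(-150, 150, 500)
        ys = rng.uniform(-150, 150, 500)
        est = np.mean([
            basal_area_from_scene(scene, (x, y), 2.0) for x, y in zip(xs, ys)
        ])
        assert est == pytest.approx(truth, rel=0.05)


class TestComposition:
    def test_identity_holds_on_real_scan(self, overstory_metrics):
        m = overstory_metrics
        assert m.ssci == pytest.approx(m.mean_frac ** math.log(m.enl), rel=1e-12)

    def test_room_scan_ssci_near_one(self):
        cfg = ScanConfig(angular_step=0.5)
        cloud = simulate_scan(_cylindrical_room(), (0, 0), cfg)
        m = compute_scan_metrics(cloud, cfg)
        assert m.mean_frac == pytest.approx(1.0, abs=0.02)
        assert m.ssci == pytest.approx(1.0, abs=0.05)
        assert m.canopy_openness == 0.0

    def test_recompute_is_bit_identical(self, overstory_scene, dome_config):
        cloud = simulate_scan(overstory_scene, (0, 0), dome_config, seed=2)
        a = compute_scan_metrics(cloud, dome_config)
        b = compute_scan_metrics(cloud, dome_config)
        assert a == b
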