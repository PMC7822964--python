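import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from ssci import (
    PredictionModel,
    Raster,
    biome_summary,
    ecoregion_keyword_filter,
    envelope_filter_by_biome,
    fit_envelope,
    apply_envelope,
    latitudinal_smooth,
    make_climate_rasters,
    predict_sscipot,
    predict_sscipot_raster,
    run_mapping,
    sample_grid,
)
from ssci.geo import haversine_km
from ssci.mapping import CLAMP_HIGH_LABEL, CLAMP_LOW_LABEL


class TestSampleGrid:
    def test_equator_ring_point_count(self):
        grid = sample_grid(spacing_km=50.0, lat_range=(-0.01, 0.01))
        assert len(grid) == int(40075.2 // 50)  # = 801

    def test_same_ring_spacing_is_50km(self, rng):
        grid = sample_grid(spacing_km=50.0, lat_range=(-70, 70))
        picks = rng.integers(0, len(grid) - 1, 1000)
        checked = 0
        for i in picks:
            a, b = grid.iloc[i], grid.iloc[i + 1]
            if a["lat"] != b["lat"]:
                continue
            d = haversine_km(a["lon"], a["lat"], b["lon"], b["lat"])
            assert d == pytest.approx(50.0, abs=1.0)
            checked += 1
        assert checked > 800

    def test_region_clipping(self):
        grid = sample_grid(region=box(0, 0, 10, 10), spacing_km=100.0)
        assert len(grid) > 0
        assert grid["lon"].between(0, 10).all()
        assert grid["lat"].between(0, 10).all()

    def test_empty_region_warns(self):
        with pytest.warns(UserWarning):
            out = sample_grid(region=Polygon(), spacing_km=100.0)
        assert out.empty

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            sample_grid(spacing_km=0.0)


class TestKeywordFilter:
    @pytest.mark.parametrize(
        "name, kept",
        [
            ("East European Forest Steppe", False),
            ("Borneo lowland rain forests", True),
            ("Central US Forest-Grassland transition", False),
            ("Scandinavian and Russian taiga", True),
            ("Zambezian Baikiaea woodlands", True),
            ("Patagonian steppe", False),
            ("Tibetan Plateau alpine meadow", False),
            ("Beni savanna", False),
        ],
    )
    def test_worked_examples(self, name, kept):
        df = pd.DataFrame({"ecoregion": [name], "lon": [0.0], "lat": [0.0]})
        out = ecoregion_keyword_filter(df)
        assert (len(out) == 1) == kept

    def test_case_insensitive(self):
        df = pd.DataFrame({"ecoregion": ["BORNEO LOWLAND RAIN FORESTS"]})
        assert len(ecoregion_keyword_filter(df)) == 1

    def test_missing_names_dropped(self):
        df = pd.DataFrame({"ecoregion": [None, "x forest"]})
        assert len(ecoregion_keyword_filter(df)) == 1


class TestEnvelope:
    def test_retention_fraction_matches_mass(self, rng):
        n = 4000
        df = pd.DataFrame({
            "MAP": rng.normal(1500, 400, n),
            "prec_seasonality": rng.normal(50, 15, n),
        })
        env = fit_envelope(df)
        flagged = apply_envelope(df, env)
        assert flagged["inside_envelope"].mean() == pytest.approx(0.95,
                                                                  abs=0.015)

    def test_far_outlier_excluded(self, rng):
        n = 500
        df = pd.DataFrame({
            "MAP": np.r_[rng.normal(1500, 100, n), 1500 + 20 * 100],
            "prec_seasonality": np.r_[rng.normal(50, 5, n), 50.0],
        })
        env = fit_envelope(df)
        flagged = apply_envelope(df, env)
        assert not flagged["inside_envelope"].iloc[-1]

    def test_per_biome_differs_from_joint(self, rng):
        # one tight and one diffuse biome: a joint fit would sacrifice the
        # diffuse cloud almost exclusively, a per-biome fit trims both by 5%
        n = 600
        a = pd.DataFrame({
            "MAP": rng.normal(500, 20, n),
            "prec_seasonality": rng.normal(20, 1, n),
            "biome": "dry",
        })
        b = pd.DataFrame({
            "MAP": rng.normal(3000, 400, n),
            "prec_seasonality": rng.normal(80, 20, n),
            "biome": "wet",
        })
        both = pd.concat([a, b], ignore_index=True)
        per_biome = envelope_filter_by_biome(both)["inside_envelope"]
        joint = apply_envelope(both, fit_envelope(both))["inside_envelope"]
        assert not per_biome.equals(joint)
        per_biome_wet = per_biome[both["biome"] == "wet"]
        joint_wet = joint[both["biome"] == "wet"]
        assert per_biome_wet.mean() > joint_wet.mean()

    def test_too_few_samples_rejected(self, rng):
        df = pd.DataFrame({"MAP": rng.normal(size=10),
                           "prec_seasonality": rng.normal(size=10)})
        with pytest.raises(ValueError, match="stable envelope"):
            fit_envelope(df)


class TestPrediction:
    MODEL = PredictionModel(intercept=0.0, coef_map=0.001,
                            coef_seasonality=-0.02)

    def test_linear_arithmetic(self):
        df = pd.DataFrame({"MAP": [3000.0], "prec_seasonality": [20.0]})
        out = predict_sscipot(df, self.MODEL)
        assert out["ssci_pot"].iloc[0] == pytest.approx(2.6)
        assert out["ssci_pot_class"].iloc[0] == ""

    def test_clamp_classes(self):
        df = pd.DataFrame({"MAP": [10300.0, 1000.0],
                           "prec_seasonality": [0.0, 0.0]})
        out = predict_sscipot(df, self.MODEL)
        assert out["ssci_pot_class"].tolist() == [CLAMP_HIGH_LABEL,
                                                  CLAMP_LOW_LABEL]

    def test_raster_prediction_matches_pixel_loop(self):
        rasters, _ = make_climate_rasters((-10, -5, 10, 5), 1.0, seed=2)
        value, cls = predict_sscipot_raster(
            rasters["MAP"], rasters["prec_seasonality"], self.MODEL
        )
        m, s = rasters["MAP"].data, rasters["prec_seasonality"].data
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                expected = 0.001 * m[i, j] - 0.02 * s[i, j]
                assert abs(value.data[i, j] - expected) < 1e-9

    def test_prediction_is_affine(self):
        df = pd.DataFrame({"MAP": [1000.0, 2000.0, 3000.0],
                           "prec_seasonality": [30.0, 30.0, 30.0]})
        v = predict_sscipot(df, self.MODEL)["ssci_pot"].to_numpy()
        # doubling MAP anomalies doubles the SSCI_pot anomalies
        assert v[2] - v[0] == pytest.approx(2 * (v[1] - v[0]))

    def test_nodata_propagates(self):
        geo = dict(xllcorner=0, yllcorner=0, cellsize=1.0, nodata=-9999.0)
        m = Raster(np.array([[1000.0, -9999.0]]), **geo)
        s = Raster(np.array([[50.0, 50.0]]), **geo)
        value, cls = predict_sscipot_raster(m, s, self.MODEL)
        assert value.data[0, 1] == -9999.0
        assert cls.data[0, 1] == -9999.0


class TestBiomeSummary:
    def test_same_distribution_shares_letter(self, rng):
        df = pd.DataFrame({
            "biome": np.repeat(["x", "y"], 60),
            "ssci_pot": rng.normal(5, 1, 120),
        })
        summary, p = biome_summary(df)
        letters = dict(zip(summary["biome"], summary["letters"]))
        assert set(letters["x"]) & set(letters["y"])

    def test_separated_groups_get_distinct_letters(self, rng):
        df = pd.DataFrame({
            "biome": np.repeat(["low", "high"], 60),
            "ssci_pot": np.r_[rng.normal(2, 0.5, 60), rng.normal(9, 0.5, 60)],
        })
        summary, p = biome_summary(df)
        letters = dict(zip(summary["biome"], summary["letters"]))
        assert not (set(letters["low"]) & set(letters["high"]))
        assert p < 1e-6

    def test_letters_invariant_to_row_order(self, rng):
        df = pd.DataFrame({
            "biome": np.repeat(["a", "b", "c"], 50),
            "ssci_pot": np.r_[rng.normal(2, 0.5, 50), rng.normal(5, 0.5, 50),
                              rng.normal(5.1, 0.5, 50)],
        })
        s1, _ = biome_summary(df)
        s2, _ = biome_summary(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_biome_gets_no_test(self, rng):
        df = pd.DataFrame({"biome": "only", "ssci_pot": rng.normal(5, 1, 30)})
        summary, p = biome_summary(df)
        assert p is None and len(summary) == 1


class TestLatitudinalSmooth:
    def test_recovers_known_smooth(self, rng):
        lat = rng.uniform(-60, 60, 400)
        noise_sd = 0.3
        y = 5 + 2 * np.cos(np.radians(3 * lat)) + rng.normal(0, noise_sd, 400)
        out = latitudinal_smooth(pd.DataFrame({"lat": lat, "ssci_pot": y}))
        interior = (out["lat"] > -55) & (out["lat"] < 55)
        truth = 5 + 2 * np.cos(np.radians(3 * out["lat"][interior]))
        approx_se = noise_sd / np.sqrt(400 / 60)
        assert np.abs(out["fit"][interior] - truth).max() < 3 * noise_sd
        assert np.all(out["upper"] >= out["lower"])

    def test_constant_response_gives_flat_fit(self, rng):
        lat = rng.uniform(-40, 40, 100)
        df = pd.DataFrame({"lat": lat, "ssci_pot": np.full(100, 4.2)})
        out = latitudinal_smooth(df)
        assert np.abs(np.diff(out["fit"])).max() < 1e-6

    def test_deterministic(self, rng):
        lat = rng.uniform(-40, 40, 120)
        df = pd.DataFrame({"lat": lat,
                           "ssci_pot": 5 + 0.01 * lat + rng.normal(0, 0.2, 120)})
        a = latitudinal_smooth(df)
        b = latitudinal_smooth(df)
        np.testing.assert_array_equal(a["fit"], b["fit"])

    def test_insufficient_span_rejected(self, rng):
        df = pd.DataFrame({"lat": rng.uniform(0, 5, 50),
                           "ssci_pot": rng.normal(5, 1, 50)})
        with pytest.raises(ValueError):
            latitudinal_smooth(df)


class TestPipelineBookkeeping:
    def test_conservation_of_samples(self):
        rasters, features = make_climate_rasters((-30, -20, 30, 20), 1.0,
                                                 seed=5)
        model = PredictionModel(intercept=2.8, coef_map=0.002,
                                coef_seasonality=-0.03)
        samples, book = run_mapping(rasters, features, model, spacing_km=100.0)
        assert book["total"] == (book["keyword_excluded"] + book["no_covariate"]
                                 + book["envelope_excluded"] + book["retained"])
        assert book["retained"] == len(samples)
        assert samples["inside_envelope"].all()
        assert {"ssci_pot", "ssci_pot_class", "biome"} <= set(samples.columns)
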