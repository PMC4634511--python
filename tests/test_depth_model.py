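"""Polygon statistics, log-linear model fitting, inversion and validation."""

import numpy as np
import pandas as pd
import pytest

import savdepth as sd
from savdepth.bands import band_by_name
from savdepth.raster import GeoTransform, ImageBand, MultiBandComposite

from conftest import make_step_scene, ols_oracle


def toy_samples(ln_dn, depths, band="NIR_R72"):
    """Single-band sample set with a prescribed ln(max DN) per sample."""
    dn = np.exp(np.asarray(ln_dn, dtype=float))
    df = pd.DataFrame(
        {
            "id": [f"t{i}" for i in range(len(dn))],
            "x": 0.0, "y": 0.0, "diameter_m": 0.185,
            "depth_cm": depths,
            f"{band}_max": dn, f"{band}_min": dn, f"{band}_mean": dn,
            f"{band}_sd": 0.0, f"{band}_count": 10, f"{band}_excluded": 0,
        }
    )
    return sd.DepthSampleSet(df, [band])


class TestExtractPolygonStats:
    def constant_composite(self, value=100.0):
        gt = GeoTransform(0, 0, 0.01)
        band = ImageBand(np.full((128, 128), value), band_by_name("NIR_R72"), gt)
        return MultiBandComposite([band], bit_depth=8)

    def polygons(self, x=0.64, y=0.64):
        return pd.DataFrame(
            {"id": ["p0"], "x": [x], "y": [y], "diameter_m": [0.2], "depth_cm": [10.0]}
        )

    def test_constant_band_statistics(self):
        s = sd.extract_polygon_stats(self.constant_composite(), self.polygons())
        row = s.data.iloc[0]
        assert row["NIR_R72_max"] == row["NIR_R72_min"] == row["NIR_R72_mean"] == 100.0
        assert row["NIR_R72_sd"] == 0.0
        assert row["NIR_R72_count"] > 0 and row["NIR_R72_excluded"] == 0

    def test_nodata_half_halves_count(self):
        comp = self.constant_composite()
        full = sd.extract_polygon_stats(comp, self.polygons()).data.iloc[0]
        comp.band("NIR_R72").dn[:, 64:] = np.nan  # polygon straddles the boundary
        half = sd.extract_polygon_stats(comp, self.polygons()).data.iloc[0]
        assert half["NIR_R72_count"] == pytest.approx(full["NIR_R72_count"] / 2, rel=0.1)
        assert half["NIR_R72_max"] == 100.0

    def test_saturated_pixels_excluded(self):
        comp = self.constant_composite(100.0)
        comp.band("NIR_R72").dn[60:68, 60:68] = 255.0
        row = sd.extract_polygon_stats(comp, self.polygons()).data.iloc[0]
        assert row["NIR_R72_max"] == 100.0
        assert row["NIR_R72_excluded"] == 64

    def test_polygon_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sd.extract_polygon_stats(self.constant_composite(), self.polygons(x=5.0))


class TestPredictorValue:
    def test_single_band_log(self):
        s = toy_samples([2.0], [10.0])
        spec = sd.PredictorSpec("single", "NIR_R72")
        assert sd.predictor_value(s.data.iloc[0], spec) == pytest.approx(2.0)

    def test_ratio_log(self):
        df = toy_samples([np.log(150.0)], [10.0]).data
        df["Red_max"] = 150.0
        df["NIR_BP2_max"] = 100.0
        spec = sd.PredictorSpec("ratio", "Red", "NIR_BP2")
        assert sd.predictor_value(df.iloc[0], spec) == pytest.approx(np.log(1.5))

    def test_ratio_with_equal_stats_is_zero(self):
        df = toy_samples([3.0], [5.0]).data
        df["Red_max"] = df["NIR_BP2_max"] = 42.0
        assert sd.predictor_value(df.iloc[0], sd.PredictorSpec("ratio", "Red", "NIR_BP2")) == 0.0

    def test_nonpositive_rejected(self):
        df = toy_samples([1.0], [5.0]).data
        df["NIR_R72_max"] = 0.0
        with pytest.raises(ValueError, match="nonpositive"):
            sd.predictor_value(df.iloc[0], sd.PredictorSpec("single", "NIR_R72"))

    def test_ratio_requires_distinct_bands(self):
        with pytest.raises(ValueError, match="distinct"):
            sd.PredictorSpec("ratio", "Red", "Red")


class TestFitDepthModel:
    def test_four_point_toy_exact(self):
        s = toy_samples([5.0, 4.8, 4.6, 4.4], [0.0, 10.0, 20.0, 30.0])
        m = sd.fit_depth_model(s, sd.PredictorSpec("single", "NIR_R72"))
        assert m.intercept == pytest.approx(5.0, abs=1e-12)
        assert m.slope == pytest.approx(-0.02, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(21)
        d = rng.uniform(5, 50, 20)
        lnv = 5.0 - 0.03 * d + rng.normal(0, 0.1, 20)
        m = sd.fit_depth_model(toy_samples(lnv, d), sd.PredictorSpec("single", "NIR_R72"))
        slope, intercept, r2 = ols_oracle(d, lnv)
        assert m.slope == pytest.approx(slope, abs=1e-12)
        assert m.intercept == pytest.approx(intercept, abs=1e-12)
        assert m.r2 == pytest.approx(r2, abs=1e-12)

    def test_duplicating_samples_keeps_coefficients(self):
        rng = np.random.default_rng(22)
        d = rng.uniform(5, 50, 10)
        lnv = 5.0 - 0.03 * d + rng.normal(0, 0.1, 10)
        m1 = sd.fit_depth_model(toy_samples(lnv, d), sd.PredictorSpec("single", "NIR_R72"))
        m2 = sd.fit_depth_model(
            toy_samples(np.r_[lnv, lnv], np.r_[d, d]), sd.PredictorSpec("single", "NIR_R72")
        )
        assert m2.slope == pytest.approx(m1.slope, abs=1e-12)
        assert m2.intercept == pytest.approx(m1.intercept, abs=1e-12)

    def test_recovers_generator_parameters_exactly(self, step_scene):
        comp, truth, polys = step_scene
        samples = sd.extract_polygon_stats(comp, polys)
        m = sd.fit_depth_model(samples, sd.PredictorSpec("single", "NIR_R72"))
        expected_a = np.log(truth.band_gain["NIR_R72"] * truth.band_rb["NIR_R72"])
        assert m.slope == pytest.approx(-truth.band_k["NIR_R72"], abs=1e-9)
        assert m.intercept == pytest.approx(expected_a, abs=1e-9)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_depth_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sd.fit_depth_model(
                toy_samples([5.0, 4.9, 4.8], [10.0, 10.0, 10.0]),
                sd.PredictorSpec("single", "NIR_R72"),
            )


class TestInvertDepth:
    def test_round_trip_on_noiseless_scene(self, step_scene):
        comp, truth, polys = step_scene
        samples = sd.extract_polygon_stats(comp, polys)
        spec = sd.PredictorSpec("single", "NIR_R72")
        m = sd.fit_depth_model(samples, spec)
        for _, row in samples.data.iterrows():
            d_e = sd.invert_depth(m, sd.predictor_value(row, spec))
            assert d_e == pytest.approx(row["depth_cm"], abs=1e-6)

    def test_zero_slope_rejected(self):
        m = sd.DepthModel(sd.PredictorSpec("single", "NIR_R72"), 5.0, 0.0, 1.0, 4, 0.0)
        with pytest.raises(ValueError, match="slope"):
            sd.invert_depth(m, 4.0)

    def test_json_round_trip(self, tmp_path):
        m = sd.DepthModel(
            sd.PredictorSpec("ratio", "Red", "NIR_BP2"), 0.4439, 0.0155, 0.73, 84,
            1e-9, stderr=0.0012,
        )
        m.to_json(tmp_path / "m.json")
        back = sd.DepthModel.from_json(tmp_path / "m.json")
        assert back == m


class TestHoldoutSplit:
    def test_sizes_and_partition(self):
        rng = np.random.default_rng(23)
        s = toy_samples(rng.normal(5, 0.2, 100), rng.uniform(5, 50, 100))
        train, test = sd.holdout_split(s, 0.15, seed=1)
        assert len(train) == 85 and len(test) == 15
        ids = set(train.data["id"]) | set(test.data["id"])
        assert len(ids) == 100
        assert not (set(train.data["id"]) & set(test.data["id"]))

    def test_seed_reproducible(self):
        rng = np.random.default_rng(24)
        s = toy_samples(rng.normal(5, 0.2, 40), rng.uniform(5, 50, 40))
        t1 = sd.holdout_split(s, 0.15, seed=9)[1].data["id"].tolist()
        t2 = sd.holdout_split(s, 0.15, seed=9)[1].data["id"].tolist()
        assert t1 == t2

    def test_bad_fraction(self):
        s = toy_samples([5.0, 4.8, 4.6], [0, 10, 20])
        with pytest.raises(ValueError, match="fraction"):
            sd.holdout_split(s, 1.2)


class TestValidate:
    def test_self_consistency_on_noiseless_scene(self, step_scene):
        comp, truth, polys = step_scene
        samples = sd.extract_polygon_stats(comp, polys)
        m = sd.fit_depth_model(samples, sd.PredictorSpec("single", "NIR_R72"))
        rep = sd.validate(m, samples)
        assert rep.slope == pytest.approx(1.0, abs=1e-9)
        assert rep.intercept == pytest.approx(0.0, abs=1e-6)
        assert rep.mae_cm == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_mean_absolute_error(self):
        # predictions {10, 20, 30} vs measured {12, 18, 33}: mae = 7/3
        s = toy_samples([10.0, 20.0, 30.0], [12.0, 18.0, 33.0])
        identity = sd.DepthModel(
            sd.PredictorSpec("single", "NIR_R72"), 0.0, 1.0, 1.0, 3, 0.0
        )
        rep = sd.validate(identity, s)
        assert rep.mae_cm == pytest.approx((2 + 2 + 3) / 3)
        assert rep.n == 3

    def test_gain_change_shifts_single_band_by_closed_form(self, step_scene):
        comp, truth, polys = step_scene
        samples = sd.extract_polygon_stats(comp, polys)
        m = sd.fit_depth_model(samples, sd.PredictorSpec("single", "NIR_R72"))
        comp2, _, _ = make_step_scene(gain_scale=0.5)
        samples2 = sd.extract_polygon_stats(comp2, polys)
        rep = sd.validate(m, samples2)
        expected_offset = np.log(2.0) / abs(m.slope)
        assert rep.slope == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(rep.residuals, expected_offset, atol=1e-6)


class TestModelMatrix:
    def test_two_band_grid(self):
        rng = np.random.default_rng(25)
        d = rng.uniform(5, 50, 15)
        df = toy_samples(5.0 - 0.03 * d + rng.normal(0, 0.05, 15), d).data
        red = 4.0 - 0.002 * d + rng.normal(0, 0.05, 15)
        df["Red_max"] = np.exp(red)
        df["Red_min"] = df["Red_max"]
        df["Red_mean"] = df["Red_max"]
        df["Red_sd"] = 0.0
        df["Red_count"] = 10
        df["Red_excluded"] = 0
        samples = sd.DepthSampleSet(df, ["NIR_R72", "Red"])
        grid = sd.model_matrix(samples, ["NIR_R72", "Red"])
        assert grid.shape == (2, 2)
        assert np.isfinite(grid.to_numpy()).all()
        assert grid.loc["Red", "NIR_R72"] == grid.loc["NIR_R72", "Red"]
        # steep NIR band should outperform the nearly depth-flat red band
        assert grid.loc["NIR_R72", "NIR_R72"] > grid.loc["Red", "Red"]

    def test_degenerate_cells_flagged_not_fatal(self):
        d = np.array([5.0, 15.0, 30.0, 45.0])
        df = toy_samples([5.0, 5.0, 5.0, 5.0], d).data  # constant DN band
        df["Red_max"] = np.exp(4.0 - 0.01 * d)
        df["Red_min"] = df["Red_max"]
        df["Red_mean"] = df["Red_max"]
        df["Red_sd"] = 0.0
        df["Red_count"] = 10
        df["Red_excluded"] = 0
        samples = sd.DepthSampleSet(df, ["NIR_R72", "Red"])
        grid = sd.model_matrix(samples, ["NIR_R72", "Red"])
        assert np.isfinite(grid.loc["Red", "Red"])

    def test_ordering_follows_attenuation_contrast(self, step_scene):
        comp, truth, polys = step_scene
        samples = sd.extract_polygon_stats(comp, polys)
        grid = sd.model_matrix(samples)
        # noiseless: every non-degenerate cell is an exact fit
        assert grid.loc["NIR_R72", "NIR_R72"] == pytest.approx(1.0, abs=1e-9)
        assert grid.loc["NIR_BP2", "Red"] == pytest.approx(1.0, abs=1e-9)
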