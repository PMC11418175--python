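"""Calibrated-photography reflectometry round trips."""

import numpy as np
import pandas as pd
import pytest

from shrimpglass.photometry import (
    CalibrationCurve,
    CalibrationStandard,
    aggregate,
    fit_calibration,
    green_channel,
    measure_standard,
    roi_mask,
    roi_reflectance,
    two_point_calibration,
)
from shrimpglass.synthetic_data import synth_photo


class TestGreenChannel:
    def test_pure_green(self):
        img = np.zeros((4, 5, 3), dtype=np.uint8)
        img[:, :, 1] = 255
        assert np.all(green_channel(img) == 255)

    def test_pure_red(self):
        img = np.zeros((4, 5, 3), dtype=np.uint8)
        img[:, :, 0] = 255
        assert np.all(green_channel(img) == 0)

    def test_known_per_pixel_values(self, rng):
        g = rng.integers(0, 256, size=(6, 7), dtype=np.uint8)
        img = np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=-1)
        assert np.array_equal(green_channel(img), g)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            green_channel(np.zeros((4, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            green_channel(np.zeros((4, 5, 3), dtype=np.uint16))


class TestCalibration:
    def test_exact_exponential_roundtrip(self):
        a, b = 0.01, 0.015
        G = np.array([40.0, 90.0, 140.0, 190.0, 240.0])
        standard = CalibrationStandard(tuple(a * np.exp(b * G)), tuple(G))
        curve = fit_calibration(standard)
        assert curve.a == pytest.approx(a, rel=1e-6)
        assert curve.b == pytest.approx(b, rel=1e-6)
        assert abs(curve.c) < 1e-9

    def test_two_point_closed_form(self):
        curve = two_point_calibration(50.0, 0.05, 200.0, 0.8)
        assert curve(50.0) == pytest.approx(0.05, rel=1e-12)
        assert curve(200.0) == pytest.approx(0.8, rel=1e-12)

    def test_degenerate_standard_rejected(self):
        with pytest.raises(ValueError):
            CalibrationStandard((0.1, 0.2, 0.3, 0.4, 0.5), (100, 100, 100, 100, 100))

    def test_non_monotone_standard_rejected(self):
        with pytest.raises(ValueError):
            CalibrationStandard((0.5, 0.2, 0.3, 0.4, 0.6), (50, 90, 140, 190, 240))

    def test_curve_monotone_over_range(self):
        curve = CalibrationCurve(0.01, 0.015, -0.005)
        g = np.linspace(0, 255, 256)
        assert np.all(np.diff(curve(g)) > 0)

    def test_decreasing_curve_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(0.01, -0.015)


class TestROI:
    def test_uniform_roi_maps_exactly_through_curve(self):
        curve = CalibrationCurve(0.01, 0.015)
        img = np.full((30, 30, 3), 120, dtype=np.uint8)
        vals = roi_reflectance(img, [{"type": "rect", "x": 2, "y": 2, "w": 10, "h": 10}], curve)
        assert vals[0] == pytest.approx(0.01 * np.exp(0.015 * 120), rel=1e-12)

    def test_polygon_mask(self):
        mask = roi_mask({"type": "polygon", "xy": [[1, 1], [8, 1], [8, 8], [1, 8]]}, (10, 10))
        assert mask.sum() > 30

    def test_roi_outside_image_rejected(self):
        curve = CalibrationCurve(0.01, 0.015)
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            roi_reflectance(img, [{"type": "rect", "x": 8, "y": 8, "w": 5, "h": 5}], curve)

    def test_extrapolation_clipped_with_warning(self):
        curve = CalibrationCurve(0.5, 0.02)
        img = np.full((10, 10, 3), 250, dtype=np.uint8)
        with pytest.warns(UserWarning, match="clip"):
            vals = roi_reflectance(img, [{"type": "rect", "x": 0, "y": 0, "w": 5, "h": 5}], curve)
        assert vals[0] == 1.0


class TestEndToEnd:
    @pytest.mark.parametrize("gamma", [1.8, 2.2, 2.4])
    def test_camera_roundtrip_recovers_antenna_reflectance(self, gamma):
        """Synthetic photo -> standard -> calibration -> ROI conversion."""
        photo = synth_photo(antenna_R=0.45, gamma=gamma, noise_sd=0.0, seed=1)
        standard = measure_standard(photo.image, photo.swatch_rois, photo.swatch_reflectances)
        curve = fit_calibration(standard)
        values = roi_reflectance(photo.image, photo.antenna_rois, curve)
        assert np.mean(values) == pytest.approx(0.45, abs=0.02)

    def test_brighter_roi_never_maps_lower(self):
        photo = synth_photo(gamma=2.2, noise_sd=2.0, seed=3)
        standard = measure_standard(photo.image, photo.swatch_rois, photo.swatch_reflectances)
        curve = fit_calibration(standard)
        g = green_channel(photo.image)
        means = sorted(float(g[roi_mask(r, g.shape)].mean()) for r in photo.antenna_rois)
        mapped = [float(curve(m)) for m in means]
        assert np.all(np.diff(mapped) >= 0)

    def test_four_of_ten_roi_subsample_is_stable(self, rng):
        """With ROI-to-ROI spread <= 0.02, any 4-ROI mean is within 0.02."""
        photo = synth_photo(antenna_R=0.45, gamma=2.2, noise_sd=1.5, seed=2)
        standard = measure_standard(photo.image, photo.swatch_rois, photo.swatch_reflectances)
        curve = fit_calibration(standard)
        values = np.array(roi_reflectance(photo.image, photo.antenna_rois, curve))
        assert values.std() <= 0.02
        for _ in range(20):
            sub = rng.choice(values, size=4, replace=False)
            assert abs(sub.mean() - values.mean()) < 0.02


class TestAggregate:
    def test_single_individual_flagged_sd(self):
        df = pd.DataFrame({
            "species": ["s"] * 2, "individual": ["i1"] * 2,
            "roi": [1, 2], "reflectance": [0.5, 0.5],
        })
        out = aggregate(df)
        assert out["mean"].iloc[0] == pytest.approx(0.5)
        assert np.isnan(out["sd"].iloc[0])
        assert not out["sd_defined"].iloc[0]

    def test_two_individual_hand_arithmetic(self):
        df = pd.DataFrame({
            "species": ["s"] * 4, "individual": ["i1", "i1", "i2", "i2"],
            "roi": [1, 2, 1, 2], "reflectance": [0.35, 0.45, 0.55, 0.65],
        })
        out = aggregate(df)
        assert out["mean"].iloc[0] == pytest.approx(0.5)
        assert out["sd"].iloc[0] == pytest.approx(np.std([0.4, 0.6], ddof=1), rel=1e-12)
        assert out["sd"].iloc[0] == pytest.approx(0.1414, abs=2e-4)

    def test_two_stage_mean_not_pooled(self):
        # individual means first: unbalanced ROI counts must not bias species mean
        df = pd.DataFrame({
            "species": ["s"] * 5, "individual": ["i1"] * 4 + ["i2"],
            "roi": [1, 2, 3, 4, 1], "reflectance": [0.4, 0.4, 0.4, 0.4, 0.6],
        })
        assert aggregate(df)["mean"].iloc[0] == pytest.approx(0.5)
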