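"""Calibrated-image pipeline: normalization, conversion, filtering, ROIs."""

import numpy as np
import pytest

from camoquant.images import (
    ROI,
    StandardPatch,
    TrialImage,
    acuity_blur,
    acuity_sigma_px,
    average_timepoints,
    measure_roi,
    normalize_with_standards,
    rnl_ranked_filter,
    to_cone_catch_image,
    trial_metrics,
)
from camoquant.observers import Observer, builtin_observer
from camoquant.rnl import ConeCatchVector, achromatic_jnd, chromatic_jnd


def make_image(pixels, scale=10.0, standards=(), meaning="camera-linear"):
    return TrialImage(pixels=np.asarray(pixels, dtype=float), channel_meaning=meaning,
                      scale_px_per_cm=scale, standards=tuple(standards))


def catch_image(pixels, obs, scale=10.0):
    img = make_image(pixels, scale=scale, meaning="reflectance")
    return to_cone_catch_image(img, obs)


@pytest.fixture()
def standards():
    return (StandardPatch((0, 4, 0, 4), 0.12), StandardPatch((0, 4, 6, 10), 0.72))


class TestNormalization:
    def test_standards_map_to_nominals_and_midpoint(self, standards):
        # camera: value = gain * reflectance + offset, per channel
        gain, offset = np.array([2.0, 0.5, 1.5]), np.array([0.1, 0.05, 0.0])
        img = np.zeros((12, 12, 3))
        img[0:4, 0:4] = 0.12 * gain + offset
        img[0:4, 6:10] = 0.72 * gain + offset
        img[6, 6] = 0.42 * gain + offset  # midpoint of the two nominals
        out = normalize_with_standards(make_image(img, standards=standards))
        assert out.channel_meaning == "reflectance"
        np.testing.assert_allclose(out.pixels[1, 1], 0.12, atol=1e-12)
        np.testing.assert_allclose(out.pixels[1, 7], 0.72, atol=1e-12)
        np.testing.assert_allclose(out.pixels[6, 6], 0.42, atol=1e-12)

    def test_measured_standard_returns_nominal(self, standards, rng):
        img = rng.uniform(0.2, 0.8, (12, 12, 3))
        img[0:4, 0:4] = 0.3
        img[0:4, 6:10] = 0.9
        out = normalize_with_standards(make_image(img, standards=standards))
        for patch in standards:
            mean = out.pixels[patch.mask((12, 12))].mean(axis=0)
            np.testing.assert_allclose(mean, patch.nominal_reflectance, atol=1e-10)

    def test_degenerate_standards_error(self, standards):
        img = np.full((12, 12, 3), 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_with_standards(make_image(img, standards=standards))


class TestConeCatchConversion:
    def test_identity_mapping_preserves_channels(self, triplefin, rng):
        px = rng.uniform(0.05, 0.9, (6, 6, 3))
        out = catch_image(px, triplefin)
        np.testing.assert_allclose(out.pixels, px)
        assert out.channel_meaning == "cone-catch"

    def test_row_normalized_mapping_preserves_neutrality(self, triplefin, rng):
        m = rng.uniform(0.1, 1.0, (3, 3))
        m /= m.sum(axis=1, keepdims=True)
        grey = np.full((4, 4, 3), 0.42)
        out = to_cone_catch_image(make_image(grey, meaning="reflectance"), triplefin, m)
        np.testing.assert_allclose(out.pixels, 0.42, rtol=1e-12)

    def test_matches_per_pixel_matrix_oracle(self, scorpionfish, rng):
        m = rng.uniform(0.1, 1.0, (2, 3))
        px = rng.uniform(0.05, 0.9, (2, 2, 3))
        out = to_cone_catch_image(make_image(px, meaning="reflectance"), scorpionfish, m)
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(out.pixels[i, j], m @ px[i, j], rtol=1e-12)

    def test_mapping_shape_mismatch(self, triplefin):
        with pytest.raises(ValueError, match="mapping shape"):
            to_cone_catch_image(make_image(np.ones((3, 3, 2)), meaning="reflectance"),
                                triplefin, np.eye(3))


class TestAcuityBlur:
    def test_sigma_formula_and_inverse_proportionality(self, triplefin):
        # px/cm=20, 30 cm, 7 cpd: sigma = (20*30*tan 1deg / 7) / 2.3548...
        sigma = acuity_sigma_px(triplefin, 20.0)
        assert sigma == pytest.approx(0.6353557358133438, rel=1e-9)
        doubled = Observer("t2", triplefin.cone_lambda_max, triplefin.cone_ratio,
                           acuity_cpd=14.0, viewing_distance_cm=30.0)
        assert acuity_sigma_px(doubled, 20.0) == pytest.approx(sigma / 2, rel=1e-12)

    def test_uniform_image_unchanged(self, goby):
        img = catch_image(np.full((16, 16, 3), 0.3), goby, scale=30.0)
        out = acuity_blur(img, goby)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_mean_preserved_and_commutes_with_scaling(self, goby, rng):
        px = rng.uniform(0.05, 0.9, (24, 24, 3))
        img = catch_image(px, goby, scale=30.0)
        out = acuity_blur(img, goby)
        for c in range(3):
            assert out.pixels[..., c].mean() == pytest.approx(
                px[..., c].mean(), rel=1e-9)
        scaled = acuity_blur(catch_image(3.0 * px, goby, scale=30.0), goby)
        np.testing.assert_allclose(scaled.pixels, 3.0 * out.pixels, rtol=1e-10)

    def test_subpixel_sigma_is_noop_with_warning(self, triplefin, rng):
        px = rng.uniform(0.05, 0.9, (8, 8, 3))
        img = catch_image(px, triplefin, scale=1.0)  # coarse sampling
        with pytest.warns(UserWarning, match="blur skipped"):
            out = acuity_blur(img, triplefin)
        np.testing.assert_array_equal(out.pixels, px)


class TestRnlRankedFilter:
    def test_uniform_image_is_fixed_point(self, scorpionfish):
        img = catch_image(np.full((10, 10, 2), 0.4)[:, :, :2], scorpionfish)
        out = rnl_ranked_filter(img, scorpionfish, radius=2, n_iter=3)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_suprathreshold_edge_preserved(self, scorpionfish):
        # two regions ~10 JND apart chromatically: boundary must not move
        px = np.empty((10, 12, 2))
        px[:, :6] = (0.2, 0.6)
        px[:, 6:] = (0.2 * np.exp(0.7), 0.6)  # df=(0.7,0) -> ~9.9 JND
        img = catch_image(px, scorpionfish)
        out = rnl_ranked_filter(img, scorpionfish, radius=2, n_iter=2)
        np.testing.assert_allclose(out.pixels, px, atol=1e-12)

    def test_subthreshold_noise_variance_shrinks(self, triplefin, rng):
        base = np.array([0.3, 0.5, 0.4])
        noise = rng.normal(0, 0.002, (20, 20, 3))  # << 1 JND
        img = catch_image(base + noise, triplefin)
        out = rnl_ranked_filter(img, triplefin, radius=2, n_iter=1)
        assert out.pixels.var() < img.pixels.var()

    def test_radius_validation(self, triplefin):
        img = catch_image(np.full((4, 4, 3), 0.3), triplefin)
        with pytest.raises(ValueError, match="radius"):
            rnl_ranked_filter(img, triplefin, radius=0)


class TestMeasureRoi:
    def test_uniform_and_mixed_masks(self, triplefin):
        px = np.full((6, 6, 3), 0.25)
        px[:3] = 0.75
        img = catch_image(px, triplefin)
        full = ROI(np.ones((6, 6), dtype=bool))
        np.testing.assert_allclose(measure_roi(img, full).q, 0.5)
        bottom = ROI(np.arange(6)[:, None] >= np.full(6, 3))
        np.testing.assert_allclose(measure_roi(img, bottom).q, 0.25)

    def test_matches_brute_force_mask_sum(self, goby, rng):
        px = rng.uniform(0.05, 1.0, (10, 10, 3))
        mask = rng.uniform(size=(10, 10)) < 0.4
        mask[0, 0] = True
        img = catch_image(px, goby)
        got = measure_roi(img, ROI(mask)).q
        expected = [px[:, :, c][mask].sum() / mask.sum() for c in range(3)]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ROI(np.zeros((4, 4), dtype=bool))


class TestTrialMetricsAndAveraging:
    def test_perfect_match_gives_zero_contrasts(self, triplefin):
        v = ConeCatchVector(triplefin, (0.2, 0.3, 0.4))
        m = trial_metrics(v, v)
        assert m["achromatic_jnd"] == 0.0 and m["chromatic_jnd"] == 0.0

    def test_pure_luminance_mismatch(self, goby):
        body = ConeCatchVector(goby, (0.6, 0.6, 0.6))
        bg = ConeCatchVector(goby, (0.2, 0.2, 0.2))
        m = trial_metrics(body, bg)
        assert m["chromatic_jnd"] == pytest.approx(0.0, abs=1e-12)
        assert m["achromatic_jnd"] > 0

    def test_composition_matches_stepwise_primitives(self, triplefin, rng):
        body = ConeCatchVector(triplefin, tuple(rng.uniform(0.1, 0.9, 3)))
        bg = ConeCatchVector(triplefin, tuple(rng.uniform(0.1, 0.9, 3)))
        m = trial_metrics(body, bg)
        assert m["achromatic_jnd"] == pytest.approx(achromatic_jnd(body, bg))
        assert m["chromatic_jnd"] == pytest.approx(chromatic_jnd(body, bg))

    def test_average_timepoints(self):
        r1 = {"fish_id": "f1", "background": "dark_grey", "luminance": 0.2, "hue": 0.30}
        r5 = {"fish_id": "f1", "background": "dark_grey", "luminance": 0.4, "hue": 0.34}
        avg = average_timepoints(r1, r5)
        assert avg["luminance"] == pytest.approx(0.3)
        assert avg["hue"] == pytest.approx(0.32)
        assert avg["fish_id"] == "f1"
        with pytest.raises(ValueError, match="differing"):
            average_timepoints(r1, {**r5, "background": "light_grey"})
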