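import numpy as np
import pytest

from cellface import (
    FcmConfig,
    SynthConfig,
    UcevSearchConfig,
    disperse_pixels,
    equalize_histogram,
    face_enhance,
    fcm_fit,
    generate_image,
    image_entropy,
    optimize_ucev,
    rgb_cluster_centers,
    rgb_to_lab,
)
from cellface.enhance import _entropy_at, clipped_fraction


def _gray(value, shape=(4, 4)):
    return np.full(shape + (3,), value, dtype=np.uint8)


@pytest.fixture(scope="module")
def enhanced_scene(default_scene):
    image, _ = default_scene
    lab = rgb_to_lab(image)
    partition = fcm_fit(lab)
    centers = rgb_cluster_centers(image, partition.memberships, 3.0)
    return image, partition, centers


class TestRgbCenters:
    def test_constant_image_centers_equal_pixel(self):
        img = _gray(90)
        u = np.random.default_rng(0).random((16, 2))
        u /= u.sum(axis=1, keepdims=True)
        c = rgb_cluster_centers(img, u, 3.0)
        assert np.allclose(c, 90.0)

    def test_crisp_two_region_image(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = 40
        img[1] = 200
        u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        c = rgb_cluster_centers(img, u, 3.0)
        assert np.allclose(sorted(c[:, 0]), [40.0, 200.0])

    def test_matches_brute_force_weighted_mean(self, rng):
        img = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        u = rng.random((16, 3))
        u /= u.sum(axis=1, keepdims=True)
        c = rgb_cluster_centers(img, u, 3.0)
        x = img.reshape(-1, 3).astype(float)
        for j in range(3):
            w = u[:, j] ** 3
            expected = (w[:, None] * x).sum(axis=0) / w.sum()
            assert np.allclose(c[j], expected, atol=1e-9)


class TestDispersion:
    def test_alpha_zero_is_identity(self, rng):
        img = rng.integers(0, 256, size=(5, 5, 3), dtype=np.uint8)
        u = rng.random((25, 2))
        u /= u.sum(axis=1, keepdims=True)
        c = rng.uniform(0, 255, size=(2, 3))
        assert np.array_equal(disperse_pixels(img, u, c, 0.0), img)

    def test_single_cluster_half_step(self):
        img = _gray(100, shape=(1, 1))
        out = disperse_pixels(img, np.array([[1.0]]), np.array([[90.0, 90.0, 90.0]]), 0.5)
        assert np.array_equal(out[0, 0], [105, 105, 105])

    def test_clamped_at_cube_face(self):
        img = np.array([[[250, 10, 10]]], dtype=np.uint8)
        out = disperse_pixels(img, np.array([[1.0]]), np.array([[200.0, 10.0, 10.0]]), 0.5)
        assert np.array_equal(out[0, 0], [255, 10, 10])

    def test_displacement_linear_in_alpha_away_from_cube_faces(self, rng):
        from cellface.enhance import _disperse_float

        # mid-range pixels and small steps so clamping never engages
        img = rng.integers(100, 156, size=(3, 3, 3), dtype=np.uint8)
        u = rng.random((9, 2))
        u /= u.sum(axis=1, keepdims=True)
        c = rng.uniform(110, 146, size=(2, 3))
        x = img.astype(float)
        d_half = _disperse_float(img, u, c, 0.5) - x
        d_one = _disperse_float(img, u, c, 1.0) - x
        assert np.allclose(d_one, 2.0 * d_half, atol=1e-9)

    def test_input_untouched(self, rng):
        img = rng.integers(0, 256, size=(3, 3, 3), dtype=np.uint8)
        ref = img.copy()
        u = np.full((9, 1), 1.0)
        disperse_pixels(img, u, np.array([[1.0, 2.0, 3.0]]), 2.0)
        assert np.array_equal(img, ref)


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert image_entropy(_gray(170), UcevSearchConfig(bins=256)) == 0.0

    def test_uniform_256_levels_exactly_8_bits(self):
        vals = np.arange(256, dtype=np.uint8).reshape(16, 16)
        img = np.repeat(vals[:, :, None], 3, axis=2)
        assert image_entropy(img, UcevSearchConfig(bins=256)) == pytest.approx(8.0, abs=1e-12)

    def test_three_level_closed_form(self):
        img = np.repeat(
            np.array([[0, 0, 128, 255]], dtype=np.uint8)[:, :, None], 3, axis=2
        )
        assert image_entropy(img, UcevSearchConfig(bins=256)) == pytest.approx(1.5, abs=1e-12)

    def test_rgb_grid_mode_counts_joint_occupancy(self):
        img = np.array(
            [[[0, 0, 0], [255, 255, 255], [0, 0, 255], [0, 0, 255]]], dtype=np.uint8
        )
        h = image_entropy(img, UcevSearchConfig(bins=2, entropy_mode="rgb_grid"))
        assert h == pytest.approx(1.5, abs=1e-12)


class TestOptimizeUcev:
    def test_entropy_star_is_max_over_samples(self, enhanced_scene):
        image, partition, centers = enhanced_scene
        curve = optimize_ucev(image, partition, centers)
        entropies = [h for _, h in curve.samples]
        assert curve.entropy_star == max(entropies)
        assert (curve.alpha_star, curve.entropy_star) in curve.samples

    def test_low_contrast_scene_gains_entropy_at_positive_alpha(self, enhanced_scene):
        image, partition, centers = enhanced_scene
        curve = optimize_ucev(image, partition, centers)
        h0 = dict(curve.samples)[0.0]
        assert curve.alpha_star > 0
        assert curve.entropy_star > h0

    def test_matches_dense_grid_oracle(self, enhanced_scene):
        image, partition, centers = enhanced_scene
        config = UcevSearchConfig()
        curve = optimize_ucev(image, partition, centers, config)
        dense = [
            (float(a), _entropy_at(image, partition.memberships, centers, float(a), config))
            for a in np.round(np.arange(-1.0, 8.0001, 0.01), 10)
        ]
        best = max(h for _, h in dense)
        alpha_oracle = min(a for a, h in dense if h == best)
        assert abs(curve.alpha_star - alpha_oracle) <= 0.05

    def test_saturated_uniform_image_keeps_alpha_zero(self):
        # image already spanning the full cube uniformly: no alpha helps
        vals = np.arange(256, dtype=np.uint8).reshape(16, 16)
        img = np.repeat(vals[:, :, None], 3, axis=2)
        lab = rgb_to_lab(img)
        partition = fcm_fit(lab, FcmConfig(k=2, subsample=0))
        centers = rgb_cluster_centers(img, partition.memberships, 3.0)
        curve = optimize_ucev(img, partition, centers, UcevSearchConfig(bins=256))
        assert curve.alpha_star == 0.0

    def test_clipped_fraction_non_decreasing_in_alpha(self, enhanced_scene):
        image, partition, centers = enhanced_scene
        fracs = [
            clipped_fraction(image, partition.memberships, centers, a)
            for a in (0.0, 1.0, 2.0, 4.0)
        ]
        assert fracs == sorted(fracs)


class TestFaceEnhance:
    def test_entropy_never_decreases_and_contrast_rises(self, default_scene):
        from cellface import rmsc

        image, _ = default_scene
        result = face_enhance(image)
        assert result.entropy_after >= result.entropy_before - 1e-9
        assert rmsc(result.enhanced) > rmsc(image)
        assert 0.0 <= result.clipped_fraction <= 1.0

    def test_constant_image_stays_constant(self):
        img = _gray(170, shape=(8, 8))
        result = face_enhance(img, FcmConfig(k=2, subsample=0))
        assert np.array_equal(result.enhanced, img)
        assert result.entropy_before == 0.0
        assert result.entropy_after == 0.0

    def test_determinism_bitwise(self, small_scene):
        image, _ = small_scene
        r1 = face_enhance(image)
        r2 = face_enhance(image)
        assert np.array_equal(r1.enhanced, r2.enhanced)
        assert r1.alpha_star == r2.alpha_star
        assert r1.curve.samples == r2.curve.samples

    def test_output_is_valid_raster(self, small_scene):
        image, _ = small_scene
        result = face_enhance(image)
        assert result.enhanced.dtype == np.uint8
        assert result.enhanced.shape == image.shape


class TestHistogramEqualization:
    def test_constant_image_unchanged(self):
        img = _gray(50)
        assert np.array_equal(equalize_histogram(img), img)

    def test_two_level_cdf_mapping(self):
        img = np.repeat(
            np.array([[50, 200], [200, 50]], dtype=np.uint8)[:, :, None], 3, axis=2
        )
        out = equalize_histogram(img)
        levels = sorted(np.unique(out))
        assert levels == [127, 255]

    def test_already_equalized_is_near_fixed_point(self):
        vals = np.arange(256, dtype=np.uint8).reshape(16, 16)
        img = np.repeat(vals[:, :, None], 3, axis=2)
        out = equalize_histogram(img)
        assert np.max(np.abs(out.astype(int) - img.astype(int))) <= 1
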