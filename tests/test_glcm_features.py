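"""GLCM construction and texture features: examples, oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from echotex import (
    FEATURE_NAMES,
    GlcmParams,
    GLCMFeaturizer,
    compute_features,
    compute_glcm,
    image_features,
    quantize_image,
)
from conftest import brute_force_glcm


class TestQuantize:
    def test_constant_maps_to_zero(self):
        out = quantize_image(np.full((3, 4), 7.3), levels=256)
        assert np.array_equal(out, np.zeros((3, 4), dtype=int))

    def test_in_range_integers_pass_through(self):
        img = np.arange(256).reshape(16, 16)
        assert np.array_equal(quantize_image(img, 256), img)

    def test_round_half_toward_zero(self):
        # {0.0, 0.5, 1.0} onto 4 levels: 0.5 scales to 1.5 -> rounds to 1
        out = quantize_image(np.array([[0.0, 0.5, 1.0]]), levels=4)
        assert out.tolist() == [[0, 1, 3]]

    def test_sixteen_bit_range_rescales(self):
        out = quantize_image(np.array([[0, 65535]], dtype=np.uint16), levels=256)
        assert out.tolist() == [[0, 255]]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty image"):
            quantize_image(np.empty((0, 0)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, max_side=8),
            elements=st.floats(-1e3, 1e3),
        )
    )
    def test_quantize_is_idempotent_and_in_range(self, raw):
        q1 = quantize_image(raw, levels=16)
        assert q1.min() >= 0 and q1.max() <= 15
        assert np.array_equal(quantize_image(q1, levels=16), q1)


class TestComputeGlcm:
    def test_constant_image_all_mass_at_origin(self):
        g = compute_glcm(np.zeros((2, 2), dtype=int), distance=1, angle=0, levels=2)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_alternating_strip_hand_enumeration(self):
        g = compute_glcm(np.array([[0, 1, 0, 1]]), distance=1, angle=0, levels=2)
        assert g.n_pairs == 6
        assert np.allclose(g.p, [[0, 0.5], [0.5, 0]])

    def test_unnormalized_counts_sum_to_n_pairs(self):
        img = np.random.default_rng(0).integers(0, 8, (12, 12))
        g = compute_glcm(img, distance=2, angle=45, levels=8, normalized=False)
        assert g.p.sum() == g.n_pairs

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="ROI too small for offset"):
            compute_glcm(np.zeros((3, 3), dtype=int), distance=5, angle=0, levels=2)

    def test_pixel_out_of_range_raises(self):
        with pytest.raises(ValueError, match="pixel exceeds gray-level range"):
            compute_glcm(np.full((4, 4), 9), distance=1, angle=0, levels=8)

    @pytest.mark.parametrize("distance", [1, 2, 5])
    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force_oracle(self, distance, angle, symmetric, normalized):
        rng = np.random.default_rng(1234)
        for _ in range(8):
            h, w = rng.integers(6, 17, size=2)
            img = rng.integers(0, 8, (h, w))
            got = compute_glcm(
                img,
                GlcmParams(distance, angle, 8, symmetric, normalized),
            )
            exp_p, exp_n = brute_force_glcm(img, distance, angle, 8, symmetric, normalized)
            assert got.n_pairs == exp_n
            np.testing.assert_array_equal(np.asarray(got.p, dtype=float), exp_p)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_skimage_symmetric(self, angle):
        """Cross-check against skimage.feature.graycomatrix.

        skimage measures angles with the row axis increasing downward, so
        under the symmetric option our angle a corresponds to skimage's
        (180 - a) mod 180.  Distance 1, where the two packages agree on the
        diagonal offset (skimage rounds sin/cos times distance, we step the
        unit diagonal `distance` times).
        """
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(7)
        img = rng.integers(0, 16, (20, 20)).astype(np.uint8)
        ours = compute_glcm(img, distance=1, angle=angle, levels=16, symmetric=True)
        sk_angle = np.deg2rad((180 - angle) % 180)
        theirs = graycomatrix(
            img, [1], [sk_angle], levels=16, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours.p, theirs, atol=1e-12)

    def test_symmetric_matrix_is_exactly_symmetric(self):
        img = np.random.default_rng(3).integers(0, 16, (15, 15))
        g = compute_glcm(img, distance=2, angle=135, levels=16, symmetric=True)
        np.testing.assert_array_equal(g.p, g.p.T)

    def test_eight_bit_glcm_is_256_square(self):
        img = np.random.default_rng(5).integers(0, 256, (32, 32))
        g = compute_glcm(img, GlcmParams())  # study defaults: d=5, 256 levels
        assert g.p.shape == (256, 256)


class TestComputeFeatures:
    def test_constant_image_degenerate_values(self):
        g = compute_glcm(np.zeros((4, 4), dtype=int), distance=1, angle=0, levels=4)
        fv = compute_features(g)
        assert fv.as_dict() == pytest.approx(
            dict(
                entropy=0, asm=1, energy=1, contrast=0,
                dissimilarity=0, homogeneity=1, correlation=1,
            )
        )

    def test_alternating_strip_hand_values(self):
        g = compute_glcm(np.array([[0, 1, 0, 1]]), distance=1, angle=0, levels=2)
        fv = compute_features(g)
        assert fv.contrast == pytest.approx(1.0)
        assert fv.dissimilarity == pytest.approx(1.0)
        assert fv.homogeneity == pytest.approx(0.5)
        assert fv.asm == pytest.approx(0.5)
        assert fv.energy == pytest.approx(np.sqrt(0.5))
        assert fv.entropy == pytest.approx(np.log(2))
        assert fv.correlation == pytest.approx(-1.0)

    def test_uniform_glcm_maximizes_entropy(self):
        L = 8
        fv = compute_features(np.full((L, L), 1 / L**2))
        assert fv.entropy == pytest.approx(2 * np.log(L))
        assert fv.asm == pytest.approx(1 / L**2)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="GLCM must be normalized"):
            compute_features(np.ones((4, 4)))

    def test_matches_skimage_graycoprops(self):
        """Feature formulas agree with the graycoprops reference."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(11)
        img = rng.integers(0, 32, (24, 24)).astype(np.uint8)
        m = graycomatrix(img, [2], [0.0], levels=32, symmetric=True, normed=True)
        fv = compute_features(m[:, :, 0, 0])
        for prop, name in [
            ("contrast", "contrast"),
            ("dissimilarity", "dissimilarity"),
            ("homogeneity", "homogeneity"),
            ("ASM", "asm"),
            ("energy", "energy"),
            ("correlation", "correlation"),
        ]:
            assert getattr(fv, name) == pytest.approx(
                float(graycoprops(m, prop)[0, 0]), rel=1e-10
            ), prop


def _random_normalized_glcm(rng, L, symmetric=False):
    m = rng.random((L, L)) * (rng.random((L, L)) < 0.4)
    if m.sum() == 0:
        m[0, 0] = 1.0
    if symmetric:
        m = m + m.T
    return m / m.sum()


class TestFeatureInvariants:
    def test_invariants_on_random_glcms(self):
        rng = np.random.default_rng(99)
        for i in range(300):
            L = int(rng.integers(2, 17))
            fv = compute_features(_random_normalized_glcm(rng, L, symmetric=i % 2 == 0))
            assert 0 < fv.asm <= 1
            assert fv.energy**2 == pytest.approx(fv.asm, abs=1e-12)
            assert 0 < fv.homogeneity <= 1
            assert 0 <= fv.entropy <= 2 * np.log(L) + 1e-12
            assert fv.contrast >= 0 and fv.dissimilarity >= 0
            assert fv.dissimilarity <= np.sqrt(fv.contrast) + 1e-12
            assert -1 - 1e-12 <= fv.correlation <= 1 + 1e-12

    def test_gray_level_translation_invariance(self):
        """Adding a constant to all pixels shifts the GLCM along the
        diagonal and must leave every feature unchanged."""
        rng = np.random.default_rng(42)
        img = rng.integers(0, 100, (30, 30))
        base = image_features(img, distance=3, angle=45, levels=256)
        shifted = image_features(img + 77, distance=3, angle=45, levels=256)
        for name in FEATURE_NAMES:
            assert getattr(shifted, name) == pytest.approx(
                getattr(base, name), abs=1e-9
            ), name

    def test_contrast_zero_iff_diagonal_iff_homogeneity_one(self):
        diag = np.diag([0.2, 0.3, 0.5])
        fv = compute_features(diag)
        assert fv.contrast == 0 and fv.homogeneity == 1
        off = np.full((3, 3), 1 / 9)
        fv2 = compute_features(off)
        assert fv2.contrast > 0 and fv2.homogeneity < 1


class TestFeaturizer:
    def test_transform_shape_and_order(self):
        rng = np.random.default_rng(0)
        imgs = [rng.integers(0, 16, (20, 20)) for _ in range(3)]
        ft = GLCMFeaturizer(distance=2, levels=16)
        X = ft.fit_transform(imgs)
        assert X.shape == (3, 7)
        assert list(ft.get_feature_names_out()) == list(FEATURE_NAMES)
        row = image_features(imgs[1], distance=2, levels=16).as_array()
        np.testing.assert_allclose(X[1], row)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        ft = GLCMFeaturizer(distance=3, angle=90, levels=32)
        ft2 = clone(ft)
        assert ft2.get_params() == ft.get_params()

    def test_angle_averaging_matches_manual_mean(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 16, (18, 18))
        avg = image_features(img, distance=2, levels=16, average_angles=True)
        manual = np.mean(
            [
                image_features(img, distance=2, angle=a, levels=16).as_array()
                for a in (0, 45, 90, 135)
            ],
            axis=0,
        )
        np.testing.assert_allclose(avg.as_array(), manual)
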