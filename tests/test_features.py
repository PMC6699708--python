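import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter
from skimage.measure import label

from melonqmon.features import (
    EmptyMaskError,
    FeatureVector,
    GlcmConfig,
    channel_stats,
    convert_channels,
    extract_features,
    glcm_matrix,
    min_area_rect,
    min_enclosing_circle,
    morphology_stats,
    quantize_gray,
    texture_stats,
)
from melonqmon.synthetic import SceneParams, ellipse_mask, generate_scene
from melonqmon.tables import FEATURE_NAMES, feature_category_counts


def brute_force_glcm(gray, mask, levels, distance, angles, symmetric=True):
    """Independent oracle: double loop over every pixel pair."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    h, w = gray.shape
    mats = []
    for angle in angles:
        dr, dc = (distance * o for o in offsets[angle])
        counts = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[gray[r, c], gray[r2, c2]] += 1
        if symmetric:
            counts = counts + counts.T
        if counts.sum() > 0:
            mats.append(counts / counts.sum())
    return np.mean(mats, axis=0)


def brute_force_texture(P):
    """Independent oracle: explicit double loop over matrix entries."""
    n = P.shape[0]
    contrast = dissim = homog = asm = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            contrast += P[i, j] * (i - j) ** 2
            dissim += P[i, j] * abs(i - j)
            homog += P[i, j] / (1 + (i - j) ** 2)
            asm += P[i, j] ** 2
            mu_i += i * P[i, j]
            mu_j += j * P[i, j]
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    if var_i * var_j > 0:
        corr = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(n) for j in range(n)
        ) / np.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return {
        "contrast": contrast,
        "dissimilarity": dissim,
        "homogeneity": homog,
        "energy": np.sqrt(asm),
        "correlation": corr,
        "asm": asm,
    }


class TestConvertChannels:
    def test_pure_red(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        ch = convert_channels(img, np.ones((1, 1), bool))
        assert ch["H"][0] == pytest.approx(0.0)
        assert ch["S"][0] == pytest.approx(1.0)
        assert ch["V"][0] == pytest.approx(1.0)

    def test_gray_is_neutral_in_lab(self):
        img = np.full((1, 1, 3), 128, dtype=np.uint8)
        ch = convert_channels(img, np.ones((1, 1), bool))
        assert abs(ch["a"][0]) < 0.5
        assert abs(ch["b"][0]) < 0.5

    def test_white_lightness(self):
        img = np.full((1, 1, 3), 255, dtype=np.uint8)
        ch = convert_channels(img, np.ones((1, 1), bool))
        assert ch["L"][0] == pytest.approx(100.0, abs=0.1)

    def test_only_foreground_pixels_used(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        ch = convert_channels(img, mask)
        assert all(len(v) == 9 for v in ch.values())
        assert np.array_equal(ch["R"], img[mask][:, 0])

    def test_empty_mask_rejected(self, rng):
        img = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        with pytest.raises(EmptyMaskError):
            convert_channels(img, np.zeros((4, 4), bool))


class TestChannelStats:
    def test_derived_example(self):
        mean, sd, median, rng_, cv = channel_stats([10, 20, 30, 40, 100])
        assert mean == pytest.approx(40.0)
        assert median == pytest.approx(30.0)
        assert rng_ == pytest.approx(90.0)
        assert sd == pytest.approx(np.sqrt(5000 / 4))  # 35.3553
        assert cv == pytest.approx(np.sqrt(5000 / 4) / 40)  # 0.8839

    def test_constant_vector(self):
        mean, sd, median, rng_, cv = channel_stats([7.0, 7.0, 7.0])
        assert (sd, rng_, cv) == (0.0, 0.0, 0.0)
        assert mean == median == 7.0

    def test_single_value(self):
        mean, sd, median, rng_, cv = channel_stats([5.0])
        assert (mean, sd, median, rng_, cv) == (5.0, 0.0, 5.0, 0.0, 0.0)

    def test_zero_mean_cv_is_zero(self):
        _, _, _, _, cv = channel_stats([-1.0, 1.0])
        assert cv == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(0.5, 1e3), min_size=2, max_size=20),
        st.floats(0.1, 100.0),
    )
    def test_cv_scale_invariant(self, values, c):
        cv1 = channel_stats(values)[4]
        cv2 = channel_stats([c * v for v in values])[4]
        assert cv2 == pytest.approx(cv1, rel=1e-9)


class TestGlcm:
    def test_two_by_two_example(self):
        gray = np.array([[0, 1], [0, 1]])
        mask = np.ones((2, 2), bool)
        P = glcm_matrix(gray, mask, GlcmConfig(levels=2, distance=1, angles=(0,)))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_two_by_two_texture_values(self):
        gray = np.array([[0, 1], [0, 1]])
        P = glcm_matrix(gray, np.ones((2, 2), bool),
                        GlcmConfig(levels=2, distance=1, angles=(0,)))
        tex = texture_stats(P)
        assert tex["contrast"] == pytest.approx(1.0)
        assert tex["dissimilarity"] == pytest.approx(1.0)
        assert tex["homogeneity"] == pytest.approx(0.5)
        assert tex["asm"] == pytest.approx(0.5)
        assert tex["energy"] == pytest.approx(np.sqrt(0.5))
        assert tex["correlation"] == pytest.approx(-1.0)

    def test_constant_image(self):
        gray = np.zeros((4, 4), dtype=int)
        P = glcm_matrix(gray, np.ones((4, 4), bool), GlcmConfig(levels=2))
        assert P[0, 0] == pytest.approx(1.0)
        tex = texture_stats(P)
        assert tex["contrast"] == 0.0
        assert tex["dissimilarity"] == 0.0
        assert tex["homogeneity"] == pytest.approx(1.0)
        assert tex["asm"] == pytest.approx(1.0)
        assert tex["energy"] == pytest.approx(1.0)
        assert tex["correlation"] == 0.0

    def test_normalization(self, rng):
        for _ in range(5):
            gray = rng.integers(0, 4, size=(8, 8))
            mask = rng.random((8, 8)) > 0.3
            P = glcm_matrix(gray, mask, GlcmConfig(levels=4))
            assert P.sum() == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        cfg = GlcmConfig(levels=4, distance=1, angles=(0, 45, 90, 135))
        for _ in range(10):
            gray = rng.integers(0, 4, size=(8, 8))
            mask = rng.random((8, 8)) > 0.2
            P = glcm_matrix(gray, mask, cfg)
            P_oracle = brute_force_glcm(gray, mask, 4, 1, cfg.angles)
            np.testing.assert_allclose(P, P_oracle, atol=1e-10)
            tex = texture_stats(P)
            tex_oracle = brute_force_texture(P_oracle)
            for key, val in tex_oracle.items():
                assert tex[key] == pytest.approx(val, abs=1e-10)

    def test_texture_bounds(self, rng):
        for _ in range(10):
            gray = rng.integers(0, 6, size=(10, 10))
            P = glcm_matrix(gray, np.ones((10, 10), bool), GlcmConfig(levels=6))
            tex = texture_stats(P)
            assert 0 < tex["homogeneity"] <= 1
            assert 0 < tex["asm"] <= 1
            assert -1 <= tex["correlation"] <= 1
            assert tex["contrast"] >= 0 and tex["dissimilarity"] >= 0

    def test_no_valid_pairs_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True  # isolated pixel: no pairs at distance 1
        with pytest.raises(ValueError, match="no valid pixel pairs"):
            glcm_matrix(np.zeros((4, 4), dtype=int), mask, GlcmConfig(levels=2))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            texture_stats(np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_masked_pairs_only(self, rng):
        # pairs that straddle the mask boundary must not count
        gray = rng.integers(0, 4, size=(10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        cfg = GlcmConfig(levels=4)
        P_full = glcm_matrix(gray, mask, cfg)
        P_crop = glcm_matrix(gray[2:8, 2:8], mask[2:8, 2:8], cfg)
        np.testing.assert_allclose(P_full, P_crop, atol=1e-12)


def filled_disk(radius, pad=5):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    return ellipse_mask((n, n), (c, c), (radius, radius))


class TestMorphology:
    def test_disk_oracle(self):
        mask = filled_disk(50)
        m = morphology_stats(mask)
        assert m["contour_area"] == pytest.approx(np.pi * 50**2, rel=0.02)
        assert m["equivalent_diameter"] == pytest.approx(100, rel=0.02)
        assert m["solidity"] >= 0.98
        assert m["aspect_ratio"] == pytest.approx(1.0, rel=0.05)
        assert m["perimeter"] == pytest.approx(2 * np.pi * 50, rel=0.05)
        assert m["r"] == pytest.approx(50, rel=0.03)

    def test_ellipse_oracle(self):
        mask = ellipse_mask((200, 200), (100, 100), (80, 40))
        m = morphology_stats(mask)
        assert m["MA"] == pytest.approx(160, rel=0.03)
        assert m["ma"] == pytest.approx(80, rel=0.03)
        assert m["extent"] == pytest.approx(np.pi / 4, rel=0.03)

    def test_square_oracle(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        m = morphology_stats(mask)
        assert m["w"] == 100 and m["h"] == 100
        assert m["extent"] == pytest.approx(1.0, rel=0.01)
        assert m["solidity"] == pytest.approx(1.0, rel=0.01)
        assert m["contour_area"] == 100 * 100
        assert m["x_w"] == pytest.approx(100, rel=0.01)
        assert m["x_h"] == pytest.approx(100, rel=0.01)
        assert m["equivalent_diameter"] == pytest.approx(np.sqrt(4e4 / np.pi))

    def test_solidity_extent_bounds_on_random_blobs(self, rng):
        count = 0
        while count < 100:
            noise = gaussian_filter(rng.random((64, 64)), 3)
            mask = noise > np.quantile(noise, 0.7)
            labels = label(mask, connectivity=2)
            if labels.max() == 0:
                continue
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            blob = labels == sizes.argmax()
            from scipy.ndimage import binary_fill_holes

            blob = binary_fill_holes(blob)
            if blob.sum() < 10:
                continue
            m = morphology_stats(blob)
            assert m["solidity"] <= 1 + 1e-6
            assert m["extent"] <= 1 + 1e-6
            assert m["hull_area"] >= m["contour_area"]
            assert m["MA"] >= m["ma"]
            assert m["aspect_ratio"] >= 1
            count += 1

    def test_rotation_robustness(self):
        mask = ellipse_mask((160, 200), (80, 100), (50, 75))
        m0 = morphology_stats(mask)
        m90 = morphology_stats(np.rot90(mask))
        assert m90["w"] == m0["h"] and m90["h"] == m0["w"]
        for key in ("contour_area", "perimeter", "equivalent_diameter"):
            assert m90[key] == pytest.approx(m0[key], rel=0.03)

    def test_multi_component_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:15] = True
        mask[30:40, 30:40] = True
        with pytest.raises(ValueError, match="single connected component"):
            morphology_stats(mask)

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            morphology_stats(np.zeros((10, 10), bool))


class TestGeometryPrimitives:
    def test_min_area_rect_of_rotated_square(self):
        # 45-degree square with corner points
        pts = np.array([[0, 10], [10, 0], [20, 10], [10, 20]], dtype=float)
        long_side, short_side = min_area_rect(pts)
        expected = 10 * np.sqrt(2)
        assert long_side == pytest.approx(expected, rel=1e-9)
        assert short_side == pytest.approx(expected, rel=1e-9)

    def test_min_enclosing_circle_of_triangle(self):
        pts = np.array([[0, 0], [0, 8], [6, 0]], dtype=float)
        c, r = min_enclosing_circle(pts)
        assert r == pytest.approx(5.0, abs=1e-9)  # circumradius of 6-8-10
        np.testing.assert_allclose(c, [3, 4], atol=1e-9)

    def test_min_enclosing_circle_contains_all(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(30, 2)) * 10
            c, r = min_enclosing_circle(pts)
            assert (np.linalg.norm(pts - c, axis=1) <= r + 1e-7).all()


class TestExtractFeatures:
    def test_length_and_split(self):
        img, mask = generate_scene(SceneParams(seed=1))
        fv = extract_features(img, mask)
        assert len(fv) == 65
        counts = feature_category_counts(fv.names)
        assert counts == {"color": 45, "texture": 6, "morphology": 14}
        assert tuple(fv.names) == FEATURE_NAMES

    def test_determinism(self):
        img, mask = generate_scene(SceneParams(seed=2))
        fv1 = extract_features(img, mask)
        fv2 = extract_features(img, mask)
        np.testing.assert_array_equal(fv1.values, fv2.values)

    def test_no_missing_values(self):
        img, mask = generate_scene(SceneParams(seed=3))
        fv = extract_features(img, mask)
        assert np.isfinite(fv.values).all()

    def test_brightness_scaling_property(self):
        # dim the scene: hue stats barely move, V mean scales by ~0.8
        params = SceneParams(seed=4, net_brightness=30)
        bright, mask = generate_scene(params)
        dim = np.clip(np.rint(bright.astype(float) * 0.8), 0, 255).astype(np.uint8)
        fb = extract_features(bright, mask).to_series()
        fd = extract_features(dim, mask).to_series()
        assert abs(fb["H_mean"] - fd["H_mean"]) < 1.0
        assert fd["V_mean"] / fb["V_mean"] == pytest.approx(0.8, abs=0.02)

    def test_background_never_contributes(self, rng):
        # extraction from a tight crop must match the full frame
        img, mask = generate_scene(
            SceneParams(image_size=(160, 160), fruit_center=(80, 80),
                        fruit_axes=(40, 40), seed=5)
        )
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        sl = np.s_[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        fv_full = extract_features(img, mask).to_series()
        fv_crop = extract_features(img[sl], mask[sl]).to_series()
        np.testing.assert_allclose(fv_full.values, fv_crop.values, rtol=1e-8, atol=1e-8)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(10))
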