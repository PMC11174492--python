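import numpy as np
import pytest

from ginkgohsi.image_features import (
    FUSION_LENGTH,
    IMAGE_LENGTH,
    FeatureVector,
    GrayImage,
    color_moments,
    extract_image_features,
    fuse,
    ggcm_features,
    glcm_features,
    gldm_features,
    hu_moments,
    tamura_features,
    to_gray,
)
from ginkgohsi.hsi_io import RgbImage, synthesize_rgb
from ginkgohsi.leaf_spectra import (
    BinaryMask,
    Spectrum,
    crop_spectrum,
    extract_mean_spectrum,
)

from _oracles import ggcm_oracle, glcm_oracle, gldm_oracle
from conftest import as_rgb, full_mask, random_gray

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def gray_of(img, mask, levels):
    return GrayImage(pixels=np.asarray(img, dtype=int), levels=levels,
                     mask=np.asarray(mask, bool))


class TestToGray:
    def test_pure_gray_equals_channel(self):
        rng = np.random.default_rng(1)
        ch = rng.uniform(0, 1, (6, 6))
        gray = to_gray(as_rgb(ch), full_mask((6, 6)), levels=8)
        # weights sum to 1 so luminance == channel; endpoints hit 0 and 7
        assert gray.pixels.min() == 0 and gray.pixels.max() == 7

    def test_range_endpoints(self):
        img = np.zeros((1, 2, 3))
        img[0, 1] = 1.0
        gray = to_gray(RgbImage(pixels=img, source_bands=(0, 1, 2)),
                       full_mask((1, 2)), levels=16)
        assert gray.pixels[0, 0] == 0 and gray.pixels[0, 1] == 15

    def test_constant_foreground_bin_zero(self):
        gray = to_gray(as_rgb(np.full((4, 4), 0.4)), full_mask((4, 4)))
        assert np.all(gray.pixels == 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            to_gray(as_rgb(np.ones((3, 3))), BinaryMask(np.zeros((3, 3), bool)))


class TestColorMoments:
    def test_constant_color(self):
        img = np.zeros((4, 4, 3))
        img[:, :, 0], img[:, :, 1], img[:, :, 2] = 0.2, 0.5, 0.8
        out = color_moments(RgbImage(pixels=img, source_bands=(0, 1, 2)),
                            full_mask((4, 4)))
        np.testing.assert_allclose(out, [0.2, 0.5, 0.8, 0, 0, 0], atol=1e-12)

    def test_population_std_hand_value(self):
        img = np.zeros((1, 2, 3))
        img[0, 0, 0], img[0, 1, 0] = 0.0, 2.0
        out = color_moments(RgbImage(pixels=img, source_bands=(0, 1, 2)),
                            full_mask((1, 2)))
        assert out[0] == pytest.approx(1.0)  # meanR
        assert out[3] == pytest.approx(1.0)  # population stdR

    def test_pixel_order_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (3, 4, 3))
        flipped = img[::-1, ::-1].copy()
        a = color_moments(RgbImage(pixels=img, source_bands=(0, 1, 2)),
                          full_mask((3, 4)))
        b = color_moments(RgbImage(pixels=flipped, source_bands=(0, 1, 2)),
                          full_mask((3, 4)))
        np.testing.assert_allclose(a, b)


class TestGlcm:
    def test_hand_worked_two_column_image(self):
        # [[0,1],[0,1]]: 2 horizontal pairs, symmetric -> P offdiag 0.5/0.5
        g = gray_of([[0, 1], [0, 1]], np.ones((2, 2)), levels=2)
        feats = glcm_features(g)
        contrast, corr, energy, homog = feats[0:4]  # angle 0
        assert contrast == pytest.approx(1.0)
        assert corr == pytest.approx(-1.0)
        assert energy == pytest.approx(0.5)
        assert homog == pytest.approx(0.5)

    def test_constant_image_conventions(self):
        g = gray_of(np.zeros((4, 4), int), np.ones((4, 4)), levels=4)
        feats = glcm_features(g).reshape(4, 4)
        for row in feats:  # every angle: contrast 0, corr 0, energy 1, homog 1
            np.testing.assert_allclose(row, [0.0, 0.0, 1.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        img, mask, levels = random_gray(seed)
        g = gray_of(img, mask, levels)
        feats = glcm_features(g).reshape(4, 4)
        for k, ang in enumerate((0, 45, 90, 135)):
            expected = glcm_oracle(img, mask, levels, _ANGLE_OFFSETS[ang])
            np.testing.assert_allclose(feats[k], expected, atol=1e-12,
                                       err_msg=f"angle {ang}")

    def test_matches_skimage_on_full_frame(self):
        # independent library cross-check, full-rectangle mask, angle 0
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(11)
        img = rng.integers(0, 6, size=(7, 7))
        g = gray_of(img, np.ones((7, 7)), levels=6)
        ours = glcm_features(g)[:4]
        P = graycomatrix(img.astype(np.uint8), [1], [0], levels=6, symmetric=True,
                         normed=True)
        theirs = [float(graycoprops(P, p)[0, 0])
                  for p in ("contrast", "correlation", "energy")]
        theirs[2] = theirs[2] ** 2  # skimage energy is sqrt of ASM
        # (homogeneity skipped: skimage uses a squared-difference denominator)
        np.testing.assert_allclose([ours[0], ours[1], ours[2]], theirs, rtol=1e-10)


class TestGgcm:
    def test_constant_image_zero_gradient(self):
        g = gray_of(np.zeros((5, 5), int), np.ones((5, 5)), levels=4)
        feats = ggcm_features(g)
        assert feats[6] == 0.0  # gradient mean
        assert feats[11] == 0.0  # gradient entropy

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        img, mask, levels = random_gray(seed)
        g = gray_of(img, mask, levels)
        np.testing.assert_allclose(
            ggcm_features(g), ggcm_oracle(img, mask, levels), atol=1e-10)

    def test_gray_entropy_matches_histogram(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, size=(10, 10))
        g = gray_of(img, np.ones((10, 10)), levels=8)
        feats = ggcm_features(g)
        inner = img[1:-1, 1:-1]  # 3x3-interior pixels on a full mask
        p = np.bincount(inner.ravel(), minlength=8) / inner.size
        p = p[p > 0]
        assert feats[10] == pytest.approx(float(-(p * np.log(p)).sum()))

    @pytest.mark.parametrize("seed", range(8))
    def test_mixing_entropy_dominates_marginals(self, seed):
        img, mask, levels = random_gray(seed)
        feats = ggcm_features(gray_of(img, mask, levels))
        gray_ent, grad_ent, mix_ent = feats[10], feats[11], feats[12]
        assert mix_ent >= max(gray_ent, grad_ent) - 1e-12


class TestGldm:
    def test_hand_worked_two_column_image(self):
        g = gray_of([[0, 1], [0, 1]], np.ones((2, 2)), levels=2)
        np.testing.assert_allclose(gldm_features(g), [1.0, 1.0, 1.0, 0.0],
                                   atol=1e-12)

    def test_constant_image(self):
        g = gray_of(np.zeros((3, 3), int), np.ones((3, 3)), levels=2)
        np.testing.assert_allclose(gldm_features(g), [0.0, 0.0, 1.0, 0.0],
                                   atol=1e-12)

    def test_no_pairs_raises(self):
        g = gray_of([[0], [1]], np.ones((2, 1)), levels=2)
        with pytest.raises(ValueError, match="pairs"):
            gldm_features(g, displacement=(0, 1))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        img, mask, levels = random_gray(seed)
        g = gray_of(img, mask, levels)
        np.testing.assert_allclose(
            gldm_features(g), gldm_oracle(img, mask, levels, (0, 1)), atol=1e-12)


class TestTamura:
    def test_constant_image_contrast_zero(self):
        g = gray_of(np.zeros((32, 32), int), np.ones((32, 32)), levels=16)
        feats = tamura_features(g)
        assert feats[1] == 0.0  # contrast
        assert feats[2] == 0.0  # directionality (no gradient)

    def test_coarseness_grows_with_block_size(self):
        def board(block):
            tile = np.indices((64, 64)).sum(axis=0) // block % 2
            return gray_of(tile * 15, np.ones((64, 64)), levels=16)

        coarse_small = tamura_features(board(2))[0]
        coarse_big = tamura_features(board(8))[0]
        assert coarse_big > coarse_small

    def test_roughness_identity(self):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 16, size=(40, 40))
        feats = tamura_features(gray_of(img, np.ones((40, 40)), levels=16))
        assert feats[4] == pytest.approx(feats[0] + feats[1], abs=1e-12)

    def test_striped_image_is_directional(self):
        stripes = np.tile(np.arange(48) // 2 % 2 * 15, (48, 1))
        feats = tamura_features(gray_of(stripes, np.ones((48, 48)), levels=16))
        rng = np.random.default_rng(4)
        noise = rng.integers(0, 16, size=(48, 48))
        nfeats = tamura_features(gray_of(noise, np.ones((48, 48)), levels=16))
        assert feats[2] > nfeats[2]  # stripes more directional than noise


class TestHuMoments:
    def test_filled_2x2_phi1(self):
        # mu20 = mu02 = 1, mu00 = 4 -> eta = 1/16 each -> phi1 = 0.125
        phis = hu_moments(BinaryMask(np.ones((2, 2), bool)))
        assert phis[0] == pytest.approx(0.125)

    def test_translation_invariance_exact(self):
        base = np.zeros((40, 40), bool)
        base[4:14, 6:12] = True
        base[8:10, 12:16] = True  # asymmetric appendage
        moved = np.zeros((40, 40), bool)
        moved[9:19, 13:19] = True
        moved[13:15, 19:23] = True  # same shape shifted by (5, 7)
        np.testing.assert_allclose(
            hu_moments(BinaryMask(base)), hu_moments(BinaryMask(moved)),
            atol=1e-12)

    def test_rotation_invariance(self):
        shape = np.zeros((60, 60), bool)
        shape[10:40, 20:30] = True
        shape[35:40, 30:45] = True  # L-shape, asymmetric
        rotated = np.rot90(shape)
        a, b = hu_moments(BinaryMask(shape)), hu_moments(BinaryMask(np.ascontiguousarray(rotated)))
        np.testing.assert_allclose(a[:6], b[:6], atol=1e-6)
        assert abs(a[6]) == pytest.approx(abs(b[6]), abs=1e-6)


class TestAssembly:
    def test_leaf_vector_length_53(self, green_leaf):
        rgb = synthesize_rgb(green_leaf.cube)
        fv = extract_image_features(rgb, green_leaf.truth_mask)
        assert len(fv) == IMAGE_LENGTH == 53

    def test_block_map_partitions(self, green_leaf):
        rgb = synthesize_rgb(green_leaf.cube)
        fv = extract_image_features(rgb, green_leaf.truth_mask)
        spans = sorted(fv.block_map.values())
        assert spans[0][0] == 0
        for (o1, l1), (o2, _) in zip(spans, spans[1:]):
            assert o1 + l1 == o2
        assert spans[-1][0] + spans[-1][1] == 53
        lengths = {k: l for k, (_, l) in fv.block_map.items()}
        assert lengths == {"color": 6, "glcm": 16, "ggcm": 15, "gldm": 4,
                           "tamura": 5, "hu": 7}

    def test_deterministic(self, green_leaf):
        rgb = synthesize_rgb(green_leaf.cube)
        a = extract_image_features(rgb, green_leaf.truth_mask)
        b = extract_image_features(rgb, green_leaf.truth_mask)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fusion_length_and_slicing(self, green_leaf):
        spec = crop_spectrum(
            extract_mean_spectrum(green_leaf.cube, green_leaf.truth_mask))
        rgb = synthesize_rgb(green_leaf.cube)
        img = extract_image_features(rgb, green_leaf.truth_mask)
        fused = fuse(spec, img)
        assert len(fused) == FUSION_LENGTH == 263
        np.testing.assert_array_equal(fused.block("spectral"), spec.values)
        np.testing.assert_array_equal(fused.values[210:], img.values)

    def test_fuse_rejects_wrong_spectral_length(self, fixture_grid, green_leaf):
        rgb = synthesize_rgb(green_leaf.cube)
        img = extract_image_features(rgb, green_leaf.truth_mask)
        bad = Spectrum(values=np.zeros(209),
                       grid=type(fixture_grid)(fixture_grid.centers[:209]))
        with pytest.raises(ValueError, match="spectral"):
            fuse(bad, img)

    def test_feature_vector_rejects_gaps(self):
        with pytest.raises(ValueError, match="gaps"):
            FeatureVector(values=np.zeros(6),
                          block_map={"a": (0, 3), "b": (2, 3)})
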