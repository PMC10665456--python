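"""CIEDE2000, entropy, SSIM and the summary/battery layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.color import deltaE_ciede2000, rgb2lab
from skimage.measure import shannon_entropy as sk_entropy

from endospect.errors import DomainError, PairingError
from endospect.metrics import (
    Ciede2000Params,
    LabColor,
    RegionMasks,
    ciede2000,
    evaluate_batch,
    region_color_difference,
    rgb_to_lab,
    shannon_entropy,
    ssim,
    summarize,
)

# Published CIEDE2000 verification pairs (Sharma, Wu & Dalal test data):
# L1, a1, b1, L2, a2, b2, expected dE00.
VERIFICATION_PAIRS = [
    (50.0000, 2.6772, -79.7751, 50.0000, 0.0000, -82.7485, 2.0425),
    (50.0000, 3.1571, -77.2803, 50.0000, 0.0000, -82.7485, 2.8615),
    (50.0000, 2.8361, -74.0200, 50.0000, 0.0000, -82.7485, 3.4412),
    (50.0000, -1.3802, -84.2814, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, -1.1848, -84.8006, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, -0.9009, -85.5211, 50.0000, 0.0000, -82.7485, 1.0000),
    (50.0000, 0.0000, 0.0000, 50.0000, -1.0000, 2.0000, 2.3669),
    (50.0000, -1.0000, 2.0000, 50.0000, 0.0000, 0.0000, 2.3669),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0009, 7.1792),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0010, 7.1792),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0011, 7.2195),
    (50.0000, 2.4900, -0.0010, 50.0000, -2.4900, 0.0012, 7.2195),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0009, -2.4900, 4.8045),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0010, -2.4900, 4.8045),
    (50.0000, -0.0010, 2.4900, 50.0000, 0.0011, -2.4900, 4.7461),
    (50.0000, 2.5000, 0.0000, 50.0000, 0.0000, -2.5000, 4.3065),
    (50.0000, 2.5000, 0.0000, 73.0000, 25.0000, -18.0000, 27.1492),
    (50.0000, 2.5000, 0.0000, 61.0000, -5.0000, 29.0000, 22.8977),
    (50.0000, 2.5000, 0.0000, 56.0000, -27.0000, -3.0000, 31.9030),
    (50.0000, 2.5000, 0.0000, 58.0000, 24.0000, 15.0000, 19.4535),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.1736, 0.5854, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.2972, 0.0000, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 1.8634, 0.5757, 1.0000),
    (50.0000, 2.5000, 0.0000, 50.0000, 3.2592, 0.3350, 1.0000),
    (60.2574, -34.0099, 36.2677, 60.4626, -34.1751, 39.4387, 1.2644),
    (63.0109, -31.0961, -5.8663, 62.8187, -29.7946, -4.0864, 1.2630),
    (61.2901, 3.7196, -5.3901, 61.4292, 2.2480, -4.9620, 1.8731),
    (35.0831, -44.1164, 3.7933, 35.0232, -40.0716, 1.5901, 1.8645),
    (22.7233, 20.0904, -46.6940, 23.0331, 14.9730, -42.5619, 2.0373),
    (36.4612, 47.8580, 18.3852, 36.2715, 50.5065, 21.2231, 1.4146),
    (90.8027, -2.0831, 1.4410, 91.1528, -1.6435, 0.0447, 1.4441),
    (90.9257, -0.5406, -0.9208, 88.6381, -0.8985, -0.7239, 1.5381),
    (6.7747, -0.2908, -2.4247, 5.8714, -0.0985, -2.2286, 0.6377),
]


class TestRgbToLab:
    def test_white_black_gray(self):
        white = rgb_to_lab(np.ones(3))
        assert white[0] == pytest.approx(100.0, abs=1e-3)
        assert abs(white[1]) < 1e-3 and abs(white[2]) < 1e-3
        black = rgb_to_lab(np.zeros(3))
        np.testing.assert_allclose(black, np.zeros(3), atol=1e-9)
        gray = rgb_to_lab(np.full(3, 0.5))
        # L from the cube-root law at relative luminance 0.21404
        assert gray[0] == pytest.approx(116 * 0.21404114048223255 ** (1 / 3) - 16, abs=1e-3)
        assert abs(gray[1]) < 1e-3 and abs(gray[2]) < 1e-3

    def test_matches_skimage_conversion(self):
        rng = np.random.default_rng(0)
        rgb = rng.uniform(0, 1, (50, 3))
        mine = rgb_to_lab(rgb)
        ref = rgb2lab(rgb.reshape(1, -1, 3))[0]
        np.testing.assert_allclose(mine, ref, atol=0.01)


class TestCiede2000:
    def test_identical_colors_give_zero(self):
        c = LabColor(43.2, 12.1, -30.5)
        assert ciede2000(c, c) == 0.0

    def test_symmetric(self):
        a = LabColor(50.0, 20.0, -34.0)
        b = LabColor(61.0, -5.0, 29.0)
        assert ciede2000(a, b) == pytest.approx(ciede2000(b, a), abs=1e-12)

    @pytest.mark.parametrize("pair", VERIFICATION_PAIRS)
    def test_published_verification_pairs(self, pair):
        L1, a1, b1, L2, a2, b2, expected = pair
        assert ciede2000((L1, a1, b1), (L2, a2, b2)) == pytest.approx(expected, abs=1e-4)

    def test_matches_independent_reference_on_random_pairs(self):
        rng = np.random.default_rng(7)
        n = 1000
        lab1 = np.column_stack(
            [rng.uniform(0, 100, n), rng.uniform(-80, 80, n), rng.uniform(-80, 80, n)]
        )
        lab2 = np.column_stack(
            [rng.uniform(0, 100, n), rng.uniform(-80, 80, n), rng.uniform(-80, 80, n)]
        )
        np.testing.assert_allclose(
            ciede2000(lab1, lab2), deltaE_ciede2000(lab1, lab2), atol=1e-6
        )

    def test_positive_for_lightness_difference(self):
        base = LabColor(50.0, 10.0, 10.0)
        shifted = LabColor(51.0, 10.0, 10.0)
        assert ciede2000(base, shifted) > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            Ciede2000Params(kL=0.0)


class TestRegionColorDifference:
    def test_identical_regions_give_zero(self):
        img = np.full((10, 10, 3), 0.5)
        masks = RegionMasks(
            np.arange(100).reshape(10, 10) < 30, np.arange(100).reshape(10, 10) >= 70
        )
        assert region_color_difference(img, masks) == 0.0

    def test_invariant_to_pixel_permutation_within_masks(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (8, 8, 3))
        vessel = np.zeros((8, 8), bool)
        vessel[:4] = True
        masks = RegionMasks(vessel, ~vessel)
        base = region_color_difference(img, masks)
        shuffled = img.copy()
        perm = rng.permutation(32)
        shuffled[:4] = shuffled[:4].reshape(32, 3)[perm].reshape(4, 8, 3)
        assert region_color_difference(shuffled, masks) == pytest.approx(base, abs=1e-9)

    def test_two_color_phantom_matches_direct_formula(self):
        c1, c2 = np.array([0.7, 0.3, 0.3]), np.array([0.4, 0.5, 0.8])
        img = np.empty((6, 6, 3))
        vessel = np.zeros((6, 6), bool)
        vessel[:3] = True
        img[vessel] = c1
        img[~vessel] = c2
        masks = RegionMasks(vessel, ~vessel)
        expected = ciede2000(rgb_to_lab(c1), rgb_to_lab(c2))
        assert region_color_difference(img, masks) == pytest.approx(expected, abs=1e-9)

    def test_disjointness_enforced(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(DomainError):
            RegionMasks(m, m)


class TestEntropy:
    def test_constant_image_has_zero_entropy(self):
        assert shannon_entropy(np.full((16, 16), 128, dtype=np.uint8)) == 0.0

    def test_equiprobable_256_levels_give_8_bits(self):
        img = np.tile(np.arange(256, dtype=np.uint8), 256).reshape(256, 256)
        assert shannon_entropy(img) == pytest.approx(8.0)

    def test_two_equiprobable_levels_give_1_bit(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:, :2] = 200
        assert shannon_entropy(img) == pytest.approx(1.0)

    def test_matches_skimage_on_uint8(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        assert shannon_entropy(img) == pytest.approx(sk_entropy(img), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=20)
    def test_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        h = shannon_entropy(img)
        assert 0.0 <= h <= 8.0
        flat = img.ravel()[rng.permutation(img.size)].reshape(img.shape)
        assert shannon_entropy(flat) == pytest.approx(h, abs=1e-12)


class TestSsim:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        assert ssim(img, img) == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        b = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        b = 255 - a
        assert -1.0 <= ssim(a, b) <= 1.0

    def test_global_mode_matches_hand_formula(self):
        """Direct evaluation of the single-window similarity on a 4x4 patch
        against its negation around the mean (zero-mean structure)."""
        patch = np.array(
            [[10.0, -3.0, 7.0, 2.0], [0.0, -9.0, 4.0, -1.0], [6.0, 1.0, -8.0, 3.0], [-5.0, 2.0, 0.0, -2.0]]
        ) + 128.0
        neg = 256.0 - patch  # negated structure, mirrored mean
        mu1, mu2 = patch.mean(), neg.mean()
        cov = np.mean((patch - mu1) * (neg - mu2))
        C1, C2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
        expected = ((2 * mu1 * mu2 + C1) * (2 * cov + C2)) / (
            (mu1**2 + mu2**2 + C1) * (patch.var() + neg.var() + C2)
        )
        got = ssim(patch, neg, mode="global")
        assert got == pytest.approx(expected, abs=1e-12)
        assert cov < 0  # structure term is genuinely negative

    def test_shape_mismatch(self):
        from endospect.errors import ShapeError

        with pytest.raises(ShapeError):
            ssim(np.zeros((8, 8)), np.zeros((9, 9)))


class TestSummarize:
    def test_single_value(self):
        s = summarize([3.2])
        assert (s.minimum, s.average, s.maximum, s.n) == (3.2, 3.2, 3.2, 1)

    def test_table_row_shape(self):
        s = summarize([2.07, 8.24, 14.91])
        assert s.minimum == 2.07 and s.maximum == 14.91

    def test_mean(self):
        assert summarize([1, 2, 3, 4]).average == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_permutation_invariant_and_exhaustive(self, values, seed):
        rng = np.random.default_rng(seed)
        s = summarize(values)
        assert s.minimum == min(values) and s.maximum == max(values)
        assert s.minimum <= s.average <= s.maximum
        perm = [values[i] for i in rng.permutation(len(values))]
        assert summarize(perm) == s


class TestEvaluateBatch:
    def test_self_ssim_is_all_ones(self):
        rng = np.random.default_rng(6)
        imgs = [rng.integers(0, 256, (32, 32, 3), dtype=np.uint8) for _ in range(3)]
        frame = evaluate_batch(
            {"a": imgs}, ssim_pairs={"a_vs_a": (imgs, imgs)}, metrics=("ssim",)
        )
        row = frame[frame.metric == "ssim"].iloc[0]
        assert row["min"] == row["avg"] == row["max"] == pytest.approx(1.0)

    def test_report_matches_composed_metric_calls(self, phantom):
        imgs = [phantom.image, phantom.image[::-1].copy()]
        masks = [phantom.masks, RegionMasks(phantom.masks.vessel[::-1], phantom.masks.background[::-1])]
        frame = evaluate_batch({"ph": imgs}, masks={"ph": masks})
        ent = frame[(frame.label == "ph") & (frame.metric == "entropy")].iloc[0]
        direct = summarize([shannon_entropy(im) for im in imgs])
        assert ent["avg"] == pytest.approx(direct.average)
        de = frame[(frame.label == "ph") & (frame.metric == "ciede2000")].iloc[0]
        direct_de = summarize([region_color_difference(im, mk) for im, mk in zip(imgs, masks)])
        assert de["min"] == pytest.approx(direct_de.minimum)
        assert de["max"] == pytest.approx(direct_de.maximum)

    def test_unpaired_ssim_rejected(self):
        a = [np.zeros((8, 8, 3), dtype=np.uint8)] * 2
        b = [np.zeros((8, 8, 3), dtype=np.uint8)] * 3
        with pytest.raises(PairingError):
            evaluate_batch({"a": a, "b": b}, ssim_pairs={"p": (a, b)}, metrics=("ssim",))
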