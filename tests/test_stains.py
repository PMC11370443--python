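"""Unit and property tests of the per-stain pixel classification rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scarquant import (
    ConfigurationError,
    StainConfig,
    classify_he,
    classify_image,
    classify_mts,
    classify_psr,
    classify_ttc,
    transform_he,
)

from naive_rules import NAIVE_RULES


def cfg(stain="MTS", **kw):
    return StainConfig(stain=stain, **kw)


class TestMts:
    def test_infarct_exemplar_blue_dominant(self):
        # R=41 well under the limit, B/R = 190/41 >> 1.2
        assert classify_mts((41, 80, 190), cfg()) is True

    def test_non_infarct_exemplar_fails_r_limit(self):
        assert classify_mts((251, 80, 190), cfg()) is False
        assert classify_mts((251, 120, 130), cfg()) is False

    def test_black_pixel_guarded_division(self):
        # epsilon guard: B/(0+1) is huge, so black classifies as infarct —
        # background exclusion is the tissue mask's job
        assert classify_mts((0, 0, 0), cfg()) is False  # B=0 < ratio
        assert classify_mts((0, 0, 255), cfg()) is True

    def test_ratio_threshold_boundary(self):
        assert classify_mts((100, 0, 120), cfg()) is True  # ratio exactly 1.2
        assert classify_mts((100, 0, 119), cfg()) is False


class TestTtc:
    def test_infarct_exemplar_near_gray(self):
        # population std of (133, 136, 134) is about 1.25
        assert classify_ttc((133, 136, 134), cfg("TTC")) is True

    def test_non_infarct_exemplar_red_dominant(self):
        # population std of (187, 69, 61) is about 57.6
        assert classify_ttc((187, 69, 61), cfg("TTC")) is False

    def test_gray_pixel_zero_variance(self):
        for v in (0, 128, 255):
            assert classify_ttc((v, v, v), cfg("TTC")) is True

    def test_population_divisor(self):
        # (0, 0, 30): mean 10, population var = (100+100+400)/3 = 200
        px = (0, 0, 30)
        assert classify_ttc(px, cfg("TTC", ttc_std_max=np.sqrt(200))) is True
        assert classify_ttc(px, cfg("TTC", ttc_std_max=np.sqrt(200) - 0.01)) is False


class TestPsr:
    def test_infarct_exemplar_red_margin(self):
        # mean_GB = (129+143)/2 = 136; margin = 104 >= 50
        assert classify_psr((240, 129, 143), cfg("PSR")) is True

    def test_non_infarct_exemplar_small_margin(self):
        # mean_GB = 182.5; margin = 21.5 < 50
        assert classify_psr((204, 191, 174), cfg("PSR")) is False

    def test_gray_pixel_zero_threshold(self):
        # R is not strictly greater than mean_GB, so even thd=0 rejects
        assert classify_psr((100, 100, 100), cfg("PSR", psr_thd=0)) is False

    def test_literal_or_reading_makes_margin_inert(self):
        c = cfg("PSR", psr_literal_or=True)
        assert classify_psr((204, 191, 174), c) is True  # any red dominance passes


class TestHe:
    def test_infarct_green_survives(self):
        img = np.array([[[150, 174, 120]]], dtype=np.uint8)
        out = transform_he(img, cfg("HE"))
        assert tuple(out[0, 0]) == (0, 174, 0)
        assert classify_he(out[0, 0], cfg("HE")) is True

    def test_non_infarct_green_removed(self):
        # R capped to 0 in step 1, so the pixel survives as (0, 99, 0) but
        # falls under the green threshold
        img = np.array([[[230, 99, 180]]], dtype=np.uint8)
        out = transform_he(img, cfg("HE"))
        assert tuple(out[0, 0]) == (0, 99, 0)
        assert classify_he(out[0, 0], cfg("HE")) is False

    def test_green_dominated_pixel_blanked(self):
        # R, B >= G after capping -> all three channels zeroed
        img = np.array([[[120, 99, 110]]], dtype=np.uint8)
        assert tuple(transform_he(img, cfg("HE"))[0, 0]) == (0, 0, 0)

    def test_all_zero_fixed_point(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        assert np.array_equal(transform_he(img, cfg("HE")), img)

    def test_green_threshold_inclusive(self):
        assert classify_he((0, 120, 0), cfg("HE")) is True
        assert classify_he((0, 119, 0), cfg("HE")) is False

    def test_transform_output_structure(self, rng):
        """Every transformed pixel is (0, g, 0) or (0, 0, 0)."""
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = transform_he(img, cfg("HE"))
        assert not out[..., 0].any() and not out[..., 2].any()


@pytest.mark.parametrize("stain", ["MTS", "TTC", "PSR", "HE"])
def test_vectorized_agrees_with_naive_loop(stain, rng):
    """Production classifiers match a literal per-pixel oracle bit-exactly."""
    c = cfg(stain)
    for _ in range(3):
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        expected = NAIVE_RULES[stain](img, c)
        got = classify_image(img, c, np.ones(img.shape[:2], dtype=bool))
        np.testing.assert_array_equal(got, expected)


@pytest.mark.parametrize(
    "stain, param, direction",
    [
        ("MTS", "mts_r_max", +1),
        ("MTS", "mts_br_ratio_min", -1),
        ("TTC", "ttc_std_max", +1),
        ("PSR", "psr_thd", -1),
        ("HE", "he_g_min", -1),
    ],
)
def test_threshold_monotonicity(stain, param, direction, rng):
    """Relaxing a permissive threshold never shrinks the infarct mask."""
    img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
    tissue = np.ones(img.shape[:2], dtype=bool)
    base = getattr(cfg(stain), param)
    values = sorted(
        (max(0.01, base + direction * d) for d in (-40, -20, 0, 20, 40)),
        reverse=direction < 0,
    )
    prev = None
    for v in values:
        mask = classify_image(img, cfg(stain, **{param: v}), tissue)
        if prev is not None:
            assert (mask | prev).sum() == mask.sum(), "mask must grow pixel-wise"
        prev = mask


class TestClassifyImage:
    def test_restricted_to_tissue(self, random_image):
        tissue = np.zeros(random_image.shape[:2], dtype=bool)
        assert not classify_image(random_image, cfg(), tissue).any()

    def test_subset_of_tissue(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        tissue = rng.random((32, 32)) < 0.5
        for stain in ("MTS", "TTC", "PSR", "HE"):
            mask = classify_image(img, cfg(stain), tissue)
            assert not (mask & ~tissue).any()

    def test_homogeneous_infarct_image(self):
        img = np.tile(np.array([41, 80, 190], dtype=np.uint8), (8, 8, 1))
        tissue = np.ones((8, 8), dtype=bool)
        assert classify_image(img, cfg("MTS"), tissue).all()

    def test_shape_mismatch_rejected(self, random_image):
        with pytest.raises(ValueError):
            classify_image(random_image, cfg(), np.ones((4, 4), dtype=bool))


class TestStainConfig:
    def test_unknown_stain_rejected(self):
        with pytest.raises(ConfigurationError, match="MTS"):
            StainConfig(stain="masson")

    def test_he_aliases_normalized(self):
        assert StainConfig(stain="h&e").stain == "HE"
        assert StainConfig(stain="mts").stain == "MTS"

    def test_threshold_ranges_validated(self):
        with pytest.raises(ConfigurationError):
            StainConfig(mts_r_max=300)
        with pytest.raises(ConfigurationError):
            StainConfig(mts_br_ratio_min=0)
        with pytest.raises(ConfigurationError):
            StainConfig(psr_thd=-1)


@given(
    r=st.integers(0, 255), g=st.integers(0, 255), b=st.integers(0, 255),
    thd=st.floats(0, 150, allow_nan=False),
)
def test_psr_conjunction_implies_literal_or(r, g, b, thd):
    """The conjunction reading only accepts pixels the literal OR accepts."""
    conj = classify_psr((r, g, b), cfg("PSR", psr_thd=thd))
    lit = classify_psr((r, g, b), cfg("PSR", psr_thd=thd, psr_literal_or=True))
    assert (not conj) or lit
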