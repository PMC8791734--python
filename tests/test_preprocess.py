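"""Weighted-scatter threshold (vs exhaustive oracle), cleanup, credible region."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteoseg import preprocess as pp


def brute_force_threshold(image, params=None):
    """Independent oracle: evaluate the scatter objective at every gray level."""
    params = params or pp.ThresholdParams()
    objs = [pp.threshold_objective(image, g, params) for g in range(1, 256)]
    return 1 + int(np.argmax(objs))  # argmax returns the first (smallest g) max


class TestComputeThreshold:
    def test_half_black_half_white(self):
        img = np.array([[0] * 8, [255] * 8], dtype=np.uint8)
        T = pp.compute_threshold(img)
        assert T == brute_force_threshold(img)
        assert 0 < T <= 255
        # any g in (0, 255] separates: tie-break must give the smallest one
        assert T == 1

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(4, 4)).astype(np.uint8)
            if img.min() == img.max():
                continue
            assert pp.compute_threshold(img) == brute_force_threshold(img)

    def test_objective_is_maximal_at_returned_threshold(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        T = pp.compute_threshold(img)
        best = pp.threshold_objective(img, T, pp.ThresholdParams())
        for g in range(1, 256):
            assert best >= pp.threshold_objective(img, g, pp.ThresholdParams()) - 1e-9

    def test_invariant_to_pixel_order(self, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
        shuffled = rng.permutation(img.ravel()).reshape(img.shape)
        assert pp.compute_threshold(img) == pp.compute_threshold(shuffled)

    def test_constant_image_degenerate(self):
        with pytest.warns(UserWarning):
            T = pp.compute_threshold(np.full((4, 4), 7, dtype=np.uint8))
        assert T == 8

    def test_default_weights(self):
        p = pp.ThresholdParams()
        assert (p.rho0, p.rho1) == (0.67, 0.33)


class TestBinarize:
    @pytest.mark.parametrize(
        "T,expected_mean", [(0, 1.0), (256, 0.0)]
    )
    def test_extremes(self, T, expected_mean, rng):
        img = rng.integers(0, 256, size=(5, 5))
        assert pp.binarize(img, T).mean() == expected_mean

    def test_direct_comparison(self):
        img = np.array([[10, 200], [30, 220]])
        assert np.array_equal(pp.binarize(img, 100), [[0, 1], [0, 1]])


class TestCleanMask:
    def test_speck_removed_and_hole_filled(self):
        m = np.zeros((12, 12), dtype=np.uint8)
        m[1, 1] = 1  # isolated speck
        m[4:10, 4:10] = 1
        m[6:8, 6:8] = 0  # interior 2x2 hole
        out = pp.clean_mask(m, min_spot_px=4, fill_holes=True)
        assert out[1, 1] == 0
        assert out[6:8, 6:8].all()

    def test_matches_flood_fill_oracle(self, rng):
        from scipy import ndimage

        m = (rng.uniform(size=(32, 32)) > 0.6).astype(np.uint8)
        out = pp.clean_mask(m, min_spot_px=5, fill_holes=False)
        # oracle: label components, keep those with >= 5 pixels
        lab, n = ndimage.label(m)
        keep = np.zeros_like(m)
        for i in range(1, n + 1):
            if (lab == i).sum() >= 5:
                keep[lab == i] = 1
        assert np.array_equal(out, keep)


class TestCredibleRegion:
    def test_single_pixel(self):
        m = np.zeros((7, 9), dtype=np.uint8)
        m[3, 5] = 1
        r = pp.credible_region(m)
        assert (r.min_x, r.max_x, r.min_y, r.max_y) == (5, 5, 3, 3)

    def test_full_mask(self):
        r = pp.credible_region(np.ones((4, 6)))
        assert (r.min_x, r.max_x, r.min_y, r.max_y) == (0, 5, 0, 3)

    def test_matches_scan_oracle(self, rng):
        m = (rng.uniform(size=(16, 16)) > 0.9).astype(np.uint8)
        if m.sum() == 0:
            m[4, 7] = 1
        r = pp.credible_region(m)
        rows, cols = np.nonzero(m)
        assert (r.min_y, r.max_y) == (rows.min(), rows.max())
        assert (r.min_x, r.max_x) == (cols.min(), cols.max())

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            pp.credible_region(np.zeros((3, 3)))

    def test_region_never_excludes_cleaned_pixels(self, rng):
        m = (rng.uniform(size=(24, 24)) > 0.7).astype(np.uint8)
        cleaned = pp.clean_mask(m, min_spot_px=4)
        if cleaned.sum() == 0:
            return
        r = pp.credible_region(cleaned)
        rows, cols = np.nonzero(cleaned)
        assert (rows >= r.min_y).all() and (rows <= r.max_y).all()
        assert (cols >= r.min_x).all() and (cols <= r.max_x).all()


class TestApplyRegion:
    def test_full_region_crop_is_identity(self, rng):
        img = rng.integers(0, 255, size=(5, 8))
        r = pp.CredibleRegion(0, 7, 0, 4)
        assert np.array_equal(pp.apply_region(img, r, "crop"), img)

    def test_zero_outside_zeroes_complement(self, rng):
        img = rng.integers(1, 255, size=(6, 6))
        r = pp.CredibleRegion(2, 4, 1, 3)
        out = pp.apply_region(img, r, "zero-outside")
        assert out.shape == img.shape
        inside = np.zeros_like(img, dtype=bool)
        inside[1:4, 2:5] = True
        assert out[~inside].sum() == 0
        assert np.array_equal(out[inside], img[inside])

    def test_crop_shape_arithmetic(self, rng):
        img = rng.integers(0, 255, size=(10, 12))
        r = pp.CredibleRegion(3, 9, 2, 6)
        assert pp.apply_region(img, r, "crop").shape == (5, 7)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            pp.apply_region(np.zeros((4, 4)), pp.CredibleRegion(0, 4, 0, 3))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_threshold_oracle_property(seed):
    """Exhaustive-scan oracle agreement on arbitrary random images."""
    img = np.random.default_rng(seed).integers(0, 256, size=(4, 4)).astype(np.uint8)
    if img.min() == img.max():
        return
    assert pp.compute_threshold(img) == brute_force_threshold(img)
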