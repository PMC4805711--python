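import math

import numpy as np
import pytest
from scipy import ndimage

import blurtex as bt
from blurtex.descriptors import (
    DESCRIPTORS,
    FEATURE_LENGTHS,
    _uniform_lut,
    ecm,
    elbp,
    lbp_uniform_hist,
    lpq,
    mfs,
    mrlbp,
)
from blurtex.measures import DegenerateImageError

from conftest import band_texture


# ---------------------------------------------------------------------------
# independent per-pixel oracles
# ---------------------------------------------------------------------------

def lbp_codes_oracle(image, radius):
    """Scalar per-pixel LBP: bilinear sampling at angles 2*pi*k/8, bit set
    when neighbor >= center.  Written with plain Python loops, independent of
    the vectorized implementation."""
    a = np.asarray(image, dtype=float)
    m = math.ceil(radius)
    h, w = a.shape
    codes = np.zeros((h - 2 * m, w - 2 * m), dtype=int)
    for r in range(m, h - m):
        for c in range(m, w - m):
            code = 0
            for k in range(8):
                ang = 2.0 * math.pi * k / 8.0
                dy = round(-radius * math.sin(ang), 8)
                dx = round(radius * math.cos(ang), 8)
                fy, fx = math.floor(dy), math.floor(dx)
                ty, tx = dy - fy, dx - fx
                y, x = r + fy, c + fx
                if tx == 0.0:
                    v0 = a[y, x]
                    v1 = a[y + 1, x] if ty != 0.0 else v0
                else:
                    v0 = a[y, x] + tx * (a[y, x + 1] - a[y, x])
                    v1 = (
                        a[y + 1, x] + tx * (a[y + 1, x + 1] - a[y + 1, x])
                        if ty != 0.0
                        else v0
                    )
                sample = v0 if ty == 0.0 else v0 + ty * (v1 - v0)
                if sample >= a[r, c]:
                    code |= 1 << k
            codes[r - m, c - m] = code
    return codes


def lpq_coeffs_oracle(image, center, window=15):
    """Direct DFT evaluation of the four LPQ coefficients at one pixel."""
    a = np.asarray(image, dtype=float)
    r = window // 2
    cy, cx = center
    coeffs = []
    for u in [(1, 0), (0, 1), (1, 1), (1, -1)]:
        acc = 0.0 + 0.0j
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                phase = -2.0j * math.pi * (u[0] * dy + u[1] * dx) / window
                acc += a[cy + dy, cx + dx] * np.exp(phase)
        coeffs.append(acc)
    return coeffs


# ---------------------------------------------------------------------------
# shared contracts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(DESCRIPTORS))
def test_length_and_normalization(name):
    vec = DESCRIPTORS[name](band_texture(0))
    assert len(vec) == FEATURE_LENGTHS[name]
    n_blocks = {"mrlbp": 2, "elbp": 1, "mfs": 3, "ecm": 1, "lpq": 1}[name]
    assert vec.sum() == pytest.approx(n_blocks, abs=1e-9)
    block = len(vec) // n_blocks
    for b in range(n_blocks):
        assert vec[b * block : (b + 1) * block].sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("name", sorted(DESCRIPTORS))
def test_deterministic(name):
    img = band_texture(1)
    np.testing.assert_array_equal(DESCRIPTORS[name](img), DESCRIPTORS[name](img.copy()))


@pytest.mark.parametrize("name", ["mrlbp", "elbp", "ecm", "lpq"])
def test_exact_invariance_to_gray_shift(name):
    # clip-free shift: texture values kept within [20, 200]
    img = np.clip(band_texture(2, contrast=0.8), 20, 200)
    np.testing.assert_array_equal(DESCRIPTORS[name](img), DESCRIPTORS[name](img + 10.0))


# ---------------------------------------------------------------------------
# LBP family
# ---------------------------------------------------------------------------

class TestLBP:
    def test_uniform_lut_partition(self):
        lut = _uniform_lut(8)
        assert lut.max() == 58 and (lut < 58).sum() == 58

    def test_constant_image_hits_single_bin(self):
        hist = lbp_uniform_hist(np.full((16, 16), 9.0), 1)
        assert (hist > 0).sum() == 1 and hist.max() == 1.0

    @pytest.mark.parametrize("radius", [1, 2])
    def test_codes_match_per_pixel_oracle(self, radius):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (16, 16))
        from blurtex.descriptors import _lbp_codes

        np.testing.assert_array_equal(_lbp_codes(img, float(radius)), lbp_codes_oracle(img, radius))

    def test_bright_center_pixel_codes(self):
        img = np.zeros((5, 5))
        img[2, 2] = 255.0
        from blurtex.descriptors import _lbp_codes

        np.testing.assert_array_equal(_lbp_codes(img, 1.0), lbp_codes_oracle(img, 1))

    def test_mrlbp_is_concatenation_of_radii(self):
        img = band_texture(4)
        vec = mrlbp(img)
        np.testing.assert_array_equal(vec[:59], lbp_uniform_hist(img, 1))
        np.testing.assert_array_equal(vec[59:], lbp_uniform_hist(img, 2))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            lbp_uniform_hist(np.zeros((3, 3)), 2)


class TestELBP:
    def test_constant_image_hits_single_bin(self):
        hist = elbp(np.full((16, 16), 50.0))
        assert (hist > 0).sum() == 1

    def test_equals_lbp_oracle_on_gradient_magnitude(self):
        img = band_texture(5, size=32)
        gx = ndimage.sobel(img, axis=1, mode="reflect")
        gy = ndimage.sobel(img, axis=0, mode="reflect")
        codes = lbp_codes_oracle(np.hypot(gx, gy), 1)
        lut = _uniform_lut(8)
        hist = np.bincount(lut[codes].ravel(), minlength=59).astype(float)
        np.testing.assert_allclose(elbp(img), hist / hist.sum(), atol=1e-12)


# ---------------------------------------------------------------------------
# MFS
# ---------------------------------------------------------------------------

class TestMFS:
    def test_constant_image_intensity_dimension_is_two(self):
        vec = mfs(np.full((32, 32), 80.0))
        intensity = vec[:26]
        # log(mu) = log c + 2 log r, so the dimension map is 2.0 up to
        # round-off: one bin carries everything and sits at dimension 2
        (idx,) = np.flatnonzero(intensity)
        assert intensity[idx] == 1.0
        bin_width = 4.0 / 26.0
        assert abs((idx + 0.5) * bin_width - 2.0) <= bin_width
        # gradient and Laplacian measures are all-zero -> dimension 0, bin 0
        assert vec[26] == 1.0 and vec[52] == 1.0

    def test_smooth_texture_dimensions_cluster_near_two(self):
        vec = mfs(band_texture(6))
        dims = np.linspace(0, 4, 27)[:-1] + 4 / 52  # bin centers
        mean_dim = float((vec[:26] * dims).sum())
        assert 1.5 < mean_dim < 2.5


# ---------------------------------------------------------------------------
# ECM
# ---------------------------------------------------------------------------

class TestECM:
    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            ecm(np.full((16, 16), 7.0))

    def test_grating_concentrates_on_diagonal(self):
        # a grating oriented along filter index 2 (pi/4): gradients all share
        # one orientation, so mass concentrates on that diagonal entry
        y, x = np.mgrid[0:64, 0:64]
        theta = math.pi / 4
        img = 127.0 + 100.0 * np.sin(2 * math.pi * 0.1 * (x * math.cos(theta) + y * math.sin(theta)))
        mat = ecm(img).reshape(8, 8)
        assert mat[2, 2] > 0.8

    def test_matches_brute_force_pair_count(self):
        img = band_texture(7, size=24)
        from blurtex.descriptors import _oriented_filters

        kernels = _oriented_filters(8, 1.0)
        resp = np.stack([ndimage.convolve(img, k, mode="reflect") for k in kernels])
        mag = np.abs(resp)
        orient = np.argmax(mag, axis=0)
        strength = np.max(mag, axis=0)
        keep = strength >= 0.25 * strength.max()
        counts = np.zeros((8, 8))
        h, w = img.shape
        for r in range(h - 1):
            for c in range(w - 1):
                if keep[r, c] and keep[r + 1, c + 1]:
                    counts[orient[r, c], orient[r + 1, c + 1]] += 1
        np.testing.assert_allclose(ecm(img), (counts / counts.sum()).ravel(), atol=1e-12)


# ---------------------------------------------------------------------------
# LPQ
# ---------------------------------------------------------------------------

class TestLPQ:
    def test_constant_image_hits_single_bin(self):
        hist = lpq(np.full((20, 20), 31.0))
        assert (hist > 0).sum() == 1

    def test_center_code_matches_direct_dft(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(8).uniform(0, 255, (17, 17)), 1.2, mode="reflect"
        )
        coeffs = lpq_coeffs_oracle(img, (8, 8))
        # guard: the oracle coefficients are far from the sign boundary
        assert min(min(abs(c.real), abs(c.imag)) for c in coeffs) > 1e-6
        code = 0
        for k, c in enumerate(coeffs):
            if c.real >= 0:
                code |= 1 << k
            if c.imag >= 0:
                code |= 1 << (k + 4)
        hist = lpq(img, window=15)
        # 17x17 image -> a 3x3 valid region; the center pixel contributes
        assert hist[code] > 0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            lpq(np.zeros((10, 10)), window=15)


def test_lpq_less_blur_sensitive_than_mrlbp(train_set, eval_set):
    """Train-clean / test-blurred at sigma = 1: the phase-based descriptor
    should lose clearly less accuracy than the intensity-pattern one."""
    from blurtex.evaluation import fit_and_score
    from blurtex.image import DegradationSpec, degrade

    blurred = [degrade(i, DegradationSpec("gaussian", sigma=1.0)) for i in eval_set.images]
    drops = {}
    for name in ("mrlbp", "lpq"):
        fn = DESCRIPTORS[name]
        Xtr = np.stack([fn(i) for i in train_set.images])
        clean = fit_and_score(Xtr, train_set.labels, np.stack([fn(i) for i in eval_set.images]), eval_set.labels)
        blur = fit_and_score(Xtr, train_set.labels, np.stack([fn(i) for i in blurred]), eval_set.labels)
        drops[name] = clean - blur
    assert drops["lpq"] < drops["mrlbp"]
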