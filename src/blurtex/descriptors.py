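"""Texture feature extractors: MRLBP, ELBP, MFS, ECM and LPQ.

Each descriptor maps a grayscale image to a fixed-length 1-D feature vector;
histogram-type outputs are L1-normalized to sum 1.  Conventions that the
underlying methods leave open are fixed explicitly so that degenerate inputs
(e.g. constant images) are well defined:

* LBP tie rule: a circular neighbor counts as 1 when neighbor >= center, so a
  constant image maps every pixel to the all-ones pattern.
* LPQ sign rule: a Fourier-coefficient component >= 0 contributes bit 1.
* Bilinear sampling is arranged so that interpolating a constant (or a
  globally shifted) image is exact in floating point, which makes the LBP
  family exactly invariant to additive gray-level shifts.

Vector lengths: MRLBP 118, ELBP 59, MFS 78 (3 x 26), ECM 64 (8x8), LPQ 256.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .measures import DegenerateImageError
from .image import as_gray

__all__ = [
    "lbp_uniform_hist",
    "mrlbp",
    "elbp",
    "mfs",
    "ecm",
    "lpq",
    "DESCRIPTORS",
    "FEATURE_LENGTHS",
]


# ---------------------------------------------------------------------------
# Uniform LBP
# ---------------------------------------------------------------------------

def _uniform_lut(neighbors: int = 8) -> np.ndarray:
    """Map each 8-bit code to its uniform-pattern bin (58 uniform + 1 joint)."""
    n_codes = 1 << neighbors
    transitions = np.empty(n_codes, dtype=np.int64)
    for code in range(n_codes):
        rotated = ((code >> 1) | (code << (neighbors - 1))) & (n_codes - 1)
        transitions[code] = bin(code ^ rotated).count("1")
    uniform_codes = np.flatnonzero(transitions <= 2)
    lut = np.full(n_codes, uniform_codes.size, dtype=np.int64)  # joint bin last
    lut[uniform_codes] = np.arange(uniform_codes.size)
    return lut


_LUT8 = _uniform_lut(8)
_N_BINS8 = 59  # 58 uniform patterns + 1 joint non-uniform bin


def _lbp_codes(image: np.ndarray, radius: float, neighbors: int = 8) -> np.ndarray:
    """Raw LBP codes on the interior pixels that have a full neighborhood.

    Neighbor k sits at angle 2*pi*k/P, sampled with bilinear interpolation
    (offsets rounded at 1e-8 so that nominally integer positions are exact).
    The interpolation is written in incremental form (a + t*(b-a)) so that
    constant inputs reproduce exactly.
    """
    a = as_gray(image)
    m = int(np.ceil(radius))
    h, w = a.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(f"image {a.shape} too small for LBP radius {radius}")
    center = a[m : h - m, m : w - m]
    codes = np.zeros(center.shape, dtype=np.int64)
    ang = 2.0 * np.pi * np.arange(neighbors) / neighbors
    dys = np.round(-radius * np.sin(ang), 8)
    dxs = np.round(radius * np.cos(ang), 8)

    def block(fy: int, fx: int) -> np.ndarray:
        return a[m + fy : h - m + fy, m + fx : w - m + fx]

    for k, (dy, dx) in enumerate(zip(dys, dxs)):
        fy, fx = int(np.floor(dy)), int(np.floor(dx))
        ty, tx = dy - fy, dx - fx
        if tx == 0.0:
            v0 = block(fy, fx)
            v1 = block(fy + 1, fx) if ty != 0.0 else v0
        else:
            v0 = block(fy, fx) + tx * (block(fy, fx + 1) - block(fy, fx))
            v1 = (
                block(fy + 1, fx) + tx * (block(fy + 1, fx + 1) - block(fy + 1, fx))
                if ty != 0.0
                else v0
            )
        sample = v0 if ty == 0.0 else v0 + ty * (v1 - v0)
        codes |= (sample >= center).astype(np.int64) << k
    return codes


def lbp_uniform_hist(image, radius: float, neighbors: int = 8) -> np.ndarray:
    """59-bin uniform-LBP histogram (8 circular neighbors, given radius)."""
    if neighbors != 8:
        raise ValueError("only the standard eight-neighborhood is supported")
    if radius not in (1, 2):
        raise ValueError("radius must be 1 or 2")
    codes = _lbp_codes(image, float(radius), neighbors)
    hist = np.bincount(_LUT8[codes].ravel(), minlength=_N_BINS8).astype(np.float64)
    return hist / hist.sum()


def mrlbp(image) -> np.ndarray:
    """Multi-resolution LBP: concatenated uniform histograms at radii 1 and 2."""
    return np.concatenate([lbp_uniform_hist(image, 1), lbp_uniform_hist(image, 2)])


def elbp(image) -> np.ndarray:
    """Edge-based LBP: uniform LBP (radius 1) on the Sobel gradient magnitude."""
    a = as_gray(image)
    if a.shape[0] < 5 or a.shape[1] < 5:
        raise ValueError("image must be at least 5x5")
    gx = ndimage.sobel(a, axis=1, mode="reflect")
    gy = ndimage.sobel(a, axis=0, mode="reflect")
    return lbp_uniform_hist(np.hypot(gx, gy), 1)


# ---------------------------------------------------------------------------
# Multi-fractal spectrum
# ---------------------------------------------------------------------------

def _disc(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (y**2 + x**2 <= r**2 + 1e-9).astype(np.float64)


def mfs(
    image,
    radii: tuple[int, ...] = (1, 2, 3, 4),
    bins_per_measure: int = 26,
    dim_range: tuple[float, float] = (0.0, 4.0),
) -> np.ndarray:
    """Multi-fractal spectrum feature (3 density measures x histogram).

    For each of three local density measures (intensity sum, Sobel
    gradient-magnitude sum, |Laplacian| sum) the disc sums mu(r) are computed
    per pixel and the local fractal dimension is the least-squares slope of
    log mu against log r.  The radius axis uses *effective* radii
    sqrt(area/pi) of the discrete discs, which removes the small-radius
    discretization bias (a constant image then has dimension exactly 2 under
    the intensity measure).  Each dimension map is histogrammed into
    ``bins_per_measure`` bins over ``dim_range`` and the three normalized
    histograms are concatenated.
    """
    a = as_gray(image)
    r_max = max(radii)
    if a.shape[0] < 2 * r_max + 1 or a.shape[1] < 2 * r_max + 1:
        raise ValueError(f"image {a.shape} too small for MFS radius {r_max}")
    discs = [_disc(r) for r in radii]
    areas = np.array([d.sum() for d in discs])
    x = 0.5 * np.log(areas / np.pi)  # log of effective radii
    xc = x - x.mean()
    coef = xc / np.dot(xc, xc)

    gx = ndimage.sobel(a, axis=1, mode="reflect")
    gy = ndimage.sobel(a, axis=0, mode="reflect")
    density_maps = [
        a,
        np.hypot(gx, gy),
        np.abs(ndimage.laplace(a, mode="reflect")),
    ]
    lo, hi = dim_range
    blocks = []
    for dmap in density_maps:
        mus = np.stack(
            [ndimage.convolve(dmap, d, mode="reflect") for d in discs], axis=0
        )
        degenerate = np.all(mus <= 0.0, axis=0)
        logs = np.log(np.clip(mus, 1e-12, None))
        dim = np.tensordot(coef, logs, axes=1)
        dim[degenerate] = 0.0
        hist, _ = np.histogram(
            np.clip(dim, lo, hi), bins=bins_per_measure, range=(lo, hi)
        )
        blocks.append(hist.astype(np.float64) / hist.sum())
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Edge co-occurrence matrix
# ---------------------------------------------------------------------------

def _oriented_filters(n_orientations: int, sigma: float) -> np.ndarray:
    """First-derivative-of-Gaussian filters at orientations k*pi/n.

    Each kernel has its mean removed so the response to a constant image is
    exactly zero (additive gray-shift invariance in floating point).
    """
    r = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    kernels = []
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        u = x * np.cos(theta) + y * np.sin(theta)
        kern = -u / sigma**2 * g
        kern -= kern.mean()
        kernels.append(kern)
    return np.stack(kernels)


def ecm(
    image,
    t_frac: float = 0.25,
    displacement: tuple[int, int] = (1, 1),
    sigma: float = 1.0,
    n_orientations: int = 8,
) -> np.ndarray:
    """Edge co-occurrence matrix over quantized gradient orientations.

    Eight oriented Gaussian-derivative filters (k*pi/8) are applied; each
    pixel takes the orientation of its strongest absolute response.  Pixels
    whose magnitude falls below ``t_frac`` of the global maximum response are
    masked out.  The L1-normalized 8x8 co-occurrence matrix of orientation
    labels at the given displacement, restricted to pairs of unmasked
    pixels, is returned flattened.
    """
    a = as_gray(image)
    if a.shape[0] < 5 or a.shape[1] < 5:
        raise ValueError("image must be at least 5x5")
    kernels = _oriented_filters(n_orientations, sigma)
    resp = np.stack([ndimage.convolve(a, k, mode="reflect") for k in kernels])
    mag = np.abs(resp)
    orient = np.argmax(mag, axis=0)
    strength = np.max(mag, axis=0)
    peak = strength.max()
    # responses to a constant image are zero up to kernel round-off
    if peak <= 1e-9 * max(1.0, float(np.abs(a).max())):
        raise DegenerateImageError("all directional responses are zero")
    unmasked = strength >= t_frac * peak
    dr, dc = displacement

    def shifted(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
        h, w = arr.shape
        return arr[max(dr, 0) : h + min(dr, 0), max(dc, 0) : w + min(dc, 0)]

    o1 = shifted(orient, -dr, -dc)  # pixel p
    o2 = shifted(orient, dr, dc)  # pixel p + v
    valid = shifted(unmasked, -dr, -dc) & shifted(unmasked, dr, dc)
    if not valid.any():
        raise DegenerateImageError("no co-occurring pair of unmasked pixels")
    pair_codes = o1[valid] * n_orientations + o2[valid]
    counts = np.bincount(pair_codes, minlength=n_orientations**2).astype(np.float64)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Local phase quantization
# ---------------------------------------------------------------------------

def _lpq_weights(window: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D STFT weights exp(-2*pi*i*x/window), mean-removed per component.

    Removing the (mathematically zero) mean makes the response to constant
    images exactly zero in floating point, fixing the sign tie rule there.
    """
    r = window // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w_re = np.cos(2.0 * np.pi * x / window)
    w_im = -np.sin(2.0 * np.pi * x / window)
    w_re -= w_re.mean()
    w_im -= w_im.mean()
    return w_re, w_im


def _correlate_complex(re, im, w_re, w_im, axis):
    """Correlate a complex field (re, im) with complex 1-D weights along axis."""
    rr = ndimage.correlate1d(re, w_re, axis=axis, mode="reflect")
    ri = ndimage.correlate1d(re, w_im, axis=axis, mode="reflect")
    ir = ndimage.correlate1d(im, w_re, axis=axis, mode="reflect")
    ii = ndimage.correlate1d(im, w_im, axis=axis, mode="reflect")
    return rr - ii, ri + ir


def lpq(image, window: int = 15) -> np.ndarray:
    """Local phase quantization histogram (256 bins), no whitening step.

    Per pixel, the short-term Fourier coefficients at the four lowest
    non-zero frequencies {(a,0), (0,a), (a,a), (a,-a)} with a = 1/window are
    computed by separable correlation over the square window; the 8-bit code
    packs the signs (>= 0 -> 1) of the four real parts (bits 0-3) and four
    imaginary parts (bits 4-7).  Only pixels with a full window contribute.
    """
    a = as_gray(image)
    window = int(window)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if a.shape[0] < window or a.shape[1] < window:
        raise ValueError(f"image {a.shape} smaller than LPQ window {window}")
    r = window // 2
    w_re, w_im = _lpq_weights(window)
    ones = np.ones(window)
    zero = np.zeros_like(a)

    # frequency (a, 0): rows carry the oscillation, columns the plain sum
    re_a0, im_a0 = _correlate_complex(a, zero, w_re, w_im, axis=0)
    re1 = ndimage.correlate1d(re_a0, ones, axis=1, mode="reflect")
    im1 = ndimage.correlate1d(im_a0, ones, axis=1, mode="reflect")
    # frequency (0, a)
    re_0a, im_0a = _correlate_complex(a, zero, w_re, w_im, axis=1)
    re2 = ndimage.correlate1d(re_0a, ones, axis=0, mode="reflect")
    im2 = ndimage.correlate1d(im_0a, ones, axis=0, mode="reflect")
    # frequency (a, a)
    re3, im3 = _correlate_complex(re_a0, im_a0, w_re, w_im, axis=1)
    # frequency (a, -a): conjugate weights along the column axis
    re4, im4 = _correlate_complex(re_a0, im_a0, w_re, -w_im, axis=1)

    comps = (re1, re2, re3, re4, im1, im2, im3, im4)
    codes = np.zeros((a.shape[0] - 2 * r, a.shape[1] - 2 * r), dtype=np.int64)
    for bit, comp in enumerate(comps):
        codes |= (comp[r:-r, r:-r] >= 0.0).astype(np.int64) << bit
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return hist / hist.sum()


DESCRIPTORS = {
    "mrlbp": mrlbp,
    "elbp": elbp,
    "mfs": mfs,
    "ecm": ecm,
    "lpq": lpq,
}

FEATURE_LENGTHS = {"mrlbp": 118, "elbp": 59, "mfs": 78, "ecm": 64, "lpq": 256}
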