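"""Grayscale image model, Gaussian kernels, convolution and blur-degradation simulators.

The universal currency of the package is a 2-D ``float64`` numpy array of
intensities on the 0-255 scale ("GrayImage").  Intensities are kept as reals
through the whole pipeline -- repeated 8-bit re-quantization between
equalization iterations would break the Gaussian semigroup property -- and are
rounded (half-even) only when an image is written to disk.

Boundary handling is symmetric (mirror) padding everywhere (scipy ``mode="reflect"``):
it avoids the dark-frame artifacts that constant padding would feed into
edge-based blur measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Kernel2D",
    "DegradationSpec",
    "as_gray",
    "gaussian_kernel",
    "delta_kernel",
    "average_kernel",
    "convolve",
    "degrade",
    "gaussian_kernel_size",
    "load_image",
    "save_image",
]

#: ITU-R 601 luminance weights used when a color image is loaded.
_LUMA = np.array([0.299, 0.587, 0.114])

#: sigma below which a Gaussian kernel degenerates to a discrete delta.
_SIGMA_EPS = 1e-6


def as_gray(pixels) -> np.ndarray:
    """Validate and coerce ``pixels`` to the 2-D float64 image convention."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class Kernel2D:
    """A small 2-D convolution kernel with odd side lengths.

    ``sigma`` records the nominal Gaussian width when the kernel was built by
    :func:`gaussian_kernel`; it is ``None`` for non-Gaussian kernels.
    """

    weights: np.ndarray
    sigma: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("kernel weights must be 2-D with odd side lengths")
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def gaussian_kernel_size(sigma: float) -> int:
    """Default truncation for a simulated Gaussian blur: 2*ceil(3*sigma)+1.

    Leaves < 0.3 % of the kernel mass outside the support before
    renormalization.
    """
    return 2 * math.ceil(3.0 * sigma) + 1


def gaussian_kernel(sigma: float, size: int | None = None) -> Kernel2D:
    """Truncated, renormalized isotropic Gaussian kernel.

    Parameters
    ----------
    sigma : nonnegative width of the Gaussian.  Below 1e-6 the kernel is the
        discrete delta (identity under convolution).
    size : odd side length; defaults to ``2*ceil(3*sigma)+1``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if size is None:
        size = gaussian_kernel_size(sigma) if sigma >= _SIGMA_EPS else 1
    size = int(size)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size}")
    if sigma < _SIGMA_EPS:
        w = np.zeros((size, size))
        w[size // 2, size // 2] = 1.0
        return Kernel2D(w, sigma=0.0)
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    w /= w.sum()
    return Kernel2D(w, sigma=float(sigma))


def delta_kernel(size: int = 1) -> Kernel2D:
    return gaussian_kernel(0.0, size)


def average_kernel(size: int) -> Kernel2D:
    size = int(size)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"averaging size must be a positive odd integer, got {size}")
    return Kernel2D(np.full((size, size), 1.0 / size**2))


def convolve(image, kernel: Kernel2D) -> np.ndarray:
    """Convolve with mirror (symmetric) boundary padding; same-size output.

    Convolving with a delta kernel returns the input bit-exactly.
    """
    img = as_gray(image)
    if kernel.shape[0] > img.shape[0] or kernel.shape[1] > img.shape[1]:
        raise ValueError(f"kernel {kernel.shape} does not fit inside image {img.shape}")
    return ndimage.convolve(img, kernel.weights, mode="reflect")


@dataclass(frozen=True)
class DegradationSpec:
    """One simulated degradation: Gaussian blur, box averaging, or median.

    ``sigma == 0`` (gaussian) and ``size == 1`` (average/median) behave as the
    exact identity, standing for the unfiltered original.
    """

    kind: str  # one of {"gaussian", "average", "median", "none"}
    sigma: float = 0.0
    size: int = 1

    def __post_init__(self):
        if self.kind not in ("gaussian", "average", "median", "none"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("filter size must be a positive odd integer")

    @property
    def is_identity(self) -> bool:
        if self.kind == "none":
            return True
        if self.kind == "gaussian":
            return self.sigma < _SIGMA_EPS
        return self.size == 1

    @property
    def level(self) -> float:
        """Scalar strength used as grid coordinate (sigma, or filter size)."""
        return float(self.sigma) if self.kind == "gaussian" else float(self.size)

    @property
    def label(self) -> str:
        if self.kind == "gaussian":
            return f"gaussian_{self.sigma:g}"
        if self.kind == "none":
            return "none"
        return f"{self.kind}_{self.size}"


def degrade(image, spec: DegradationSpec) -> np.ndarray:
    """Apply a :class:`DegradationSpec`; identity specs return the input unchanged."""
    img = as_gray(image)
    if spec.is_identity:
        return img
    if spec.kind == "gaussian":
        return convolve(img, gaussian_kernel(spec.sigma))
    if spec.kind == "average":
        return convolve(img, average_kernel(spec.size))
    # median
    return ndimage.median_filter(img, size=spec.size, mode="reflect")


# ---------------------------------------------------------------------------
# File I/O (PNG / TIFF / PGM readers, 8-bit PNG writer)
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read a raster image; color inputs are reduced to ITU-R 601 luminance."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    arr = raw[..., :3].astype(np.float64) @ _LUMA if raw.ndim == 3 else raw.astype(np.float64)
    if np.issubdtype(raw.dtype, np.floating) and arr.size and arr.max() <= 1.0:
        arr = arr * 255.0  # unit-range float rasters onto the 0-255 scale
    return as_gray(arr)


def save_image(path, image) -> None:
    """Write an 8-bit PNG (or other raster by extension), rounding half-even."""
    import imageio.v3 as iio

    img = as_gray(image)
    quantized = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    iio.imwrite(path, quantized)
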