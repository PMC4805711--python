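"""No-reference blur measures and decile threshold computation.

Three scalar blur measures are provided, all *oriented* so that a larger
score means a blurrier image (the orientation contract).  This keeps the
equalization stop test ``B(I) >= theta`` literal for every measure:

``measure_marziliano`` (id ``"ma"``)
    mean vertical-edge width divided by mean edge magnitude; blurred edges
    are long and shallow, so the ratio grows with blur.
``measure_crete`` (id ``"cr"``)
    compares neighbor intensity variations of the image with those of a
    3x3-average low-pass version; a score in [0, 1], near 1 when low-pass
    filtering no longer removes variation (the image was already blurred).
``measure_contrast`` (id ``"co"``)
    mean squared difference of horizontal/vertical neighbor gray values,
    *negated* (contrast shrinks with blur, so the negation satisfies the
    orientation contract; thresholds live in the negated space).

Thresholds are the first to tenth ten-quantiles of the scores of a reference
image set, under the inclusive linear-interpolation quantile convention, so
they are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy import ndimage

from .image import DegradationSpec, as_gray, degrade

__all__ = [
    "BlurScore",
    "ThresholdSet",
    "DegenerateImageError",
    "measure_marziliano",
    "measure_crete",
    "measure_contrast",
    "MEASURES",
    "get_measure",
    "compute_thresholds",
]


class DegenerateImageError(ValueError):
    """Raised when a measure is undefined on an image (e.g. no edges, constant).

    ``treat_as_max_blur`` flags that a caller may sensibly treat the image as
    maximally blurred (a constant image is the limit of infinite blurring).
    """

    def __init__(self, message: str, treat_as_max_blur: bool = True):
        super().__init__(message)
        self.treat_as_max_blur = treat_as_max_blur


@dataclass(frozen=True)
class BlurScore:
    """Oriented scalar blurriness: larger value = blurrier image."""

    value: float
    measure_id: str


def _run_bounds(a: np.ndarray, strict_increasing: bool):
    """Per-pixel bounds of the strictly monotone run containing each column.

    For every pixel (r, c) returns L[r, c] (leftmost column reachable by
    walking left while the row stays strictly increasing up to c) and
    R[r, c] (rightmost column reachable walking right).  Plateaus break runs,
    which collapses them onto their endpoint closest to the query pixel.
    """
    h, w = a.shape
    idx = np.broadcast_to(np.arange(w), (h, w))
    if strict_increasing:
        step = a[:, 1:] > a[:, :-1]
    else:
        step = a[:, 1:] < a[:, :-1]
    cont_left = np.zeros((h, w), dtype=bool)
    cont_left[:, 1:] = step  # run continues from c-1 to c
    cont_right = np.zeros((h, w), dtype=bool)
    cont_right[:, :-1] = step  # run continues from c to c+1
    left = np.maximum.accumulate(np.where(cont_left, 0, idx), axis=1)
    right_rev = np.where(cont_right, w - 1, idx)[:, ::-1]
    right = np.minimum.accumulate(right_rev, axis=1)[:, ::-1]
    return left, right


def measure_marziliano(image, edge_threshold_frac: float = 0.1) -> BlurScore:
    """Edge-width based blur measure.

    Vertical edges are detected with the horizontal Sobel derivative; edge
    pixels are those whose magnitude exceeds ``edge_threshold_frac`` of the
    image's maximum response (a sharpness-independent relative cutoff).  For
    each edge pixel, its row is scanned left/right to the nearest strict
    local extrema; the edge length is the distance between the two extrema
    and the edge magnitude the absolute gray-value difference between them.
    The score is mean(length) / mean(magnitude).
    """
    a = as_gray(image)
    gx = ndimage.sobel(a, axis=1, mode="reflect")
    max_mag = np.abs(gx).max()
    if max_mag == 0:
        raise DegenerateImageError("no vertical edges detected (flat image)")
    edge = np.abs(gx) > edge_threshold_frac * max_mag
    rows, cols = np.nonzero(edge)
    if rows.size == 0:
        raise DegenerateImageError("no vertical edges above the magnitude cutoff")
    l_rise, r_rise = _run_bounds(a, strict_increasing=True)
    l_fall, r_fall = _run_bounds(a, strict_increasing=False)
    rising = gx[rows, cols] > 0
    left = np.where(rising, l_rise[rows, cols], l_fall[rows, cols])
    right = np.where(rising, r_rise[rows, cols], r_fall[rows, cols])
    widths = (right - left).astype(np.float64)
    mags = np.abs(a[rows, right] - a[rows, left])
    mean_mag = mags.mean()
    if mean_mag == 0:
        raise DegenerateImageError("all detected edges have zero extremum magnitude")
    return BlurScore(float(widths.mean() / mean_mag), "ma")


_BOX3 = DegradationSpec("average", size=3)


def measure_crete(image) -> BlurScore:
    """Low-pass comparison blur measure, in [0, 1].

    Sums of absolute neighbor differences are computed per direction for the
    input and for its 3x3-average filtered version; the per-direction blur is
    the fraction of variation *not* removed by the low-pass step, and the
    score is the maximum over the horizontal and vertical directions.
    Directions with zero original variation are skipped.
    """
    a = as_gray(image)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    b = degrade(a, _BOX3)
    scores = []
    for axis in (0, 1):
        d_orig = np.abs(np.diff(a, axis=axis))
        total = d_orig.sum()
        if total == 0:
            continue
        d_blur = np.abs(np.diff(b, axis=axis))
        removed = np.maximum(0.0, d_orig - d_blur).sum()
        scores.append((total - removed) / total)
    if not scores:
        raise DegenerateImageError("image is constant; neighbor variation is zero")
    return BlurScore(float(max(scores)), "cr")


def measure_contrast(image) -> BlurScore:
    """Negated mean squared neighbor difference.

    The raw contrast C (mean of squared horizontal and vertical neighbor
    differences, normalized by the pair count so mixed image sizes compare)
    shrinks under blur, so the score is ``-C``.
    """
    a = as_gray(image)
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    dh = np.diff(a, axis=1)
    dv = np.diff(a, axis=0)
    n_pairs = dh.size + dv.size
    c = (np.sum(dh**2) + np.sum(dv**2)) / n_pairs
    return BlurScore(float(-c), "co")


MEASURES: dict[str, Callable[[np.ndarray], BlurScore]] = {
    "ma": measure_marziliano,
    "cr": measure_crete,
    "co": measure_contrast,
}


def get_measure(measure) -> tuple[str, Callable[[np.ndarray], BlurScore]]:
    """Resolve a measure id or callable to ``(measure_id, function)``."""
    if callable(measure):
        mid = getattr(measure, "measure_id", getattr(measure, "__name__", "custom"))
        return str(mid), measure
    key = str(measure).lower()
    if key not in MEASURES:
        raise ValueError(f"unknown blur measure {measure!r}; choose from {sorted(MEASURES)}")
    return key, MEASURES[key]


@dataclass(frozen=True)
class ThresholdSet:
    """The ten decile thresholds of a reference score distribution.

    ``thetas[k-1]`` is the k/10-quantile (k = 1..10) of the source scores;
    ``thetas[9]`` is the maximum score.  Always non-decreasing.
    """

    thetas: np.ndarray
    measure_id: str
    source_n: int

    def theta(self, quantile_index: int) -> float:
        """Threshold for decile ``quantile_index`` in 1..10."""
        if not 1 <= quantile_index <= 10:
            raise ValueError("quantile index must be in 1..10")
        return float(self.thetas[quantile_index - 1])


def compute_thresholds(scores: Iterable, measure_id: str | None = None) -> ThresholdSet:
    """Decile thresholds from a collection of scores.

    Accepts :class:`BlurScore` objects (which must share one ``measure_id``)
    or raw floats (then ``measure_id`` must be given).  Uses the inclusive
    linear-interpolation quantile convention.
    """
    scores = list(scores)
    if len(scores) < 10:
        raise ValueError("need at least 10 scores to form decile thresholds")
    values = []
    for s in scores:
        if isinstance(s, BlurScore):
            if measure_id is None:
                measure_id = s.measure_id
            elif s.measure_id != measure_id:
                raise ValueError(
                    f"mixed measure ids: {s.measure_id!r} vs {measure_id!r}"
                )
            values.append(s.value)
        else:
            values.append(float(s))
    if measure_id is None:
        raise ValueError("measure_id required when passing raw score values")
    arr = np.asarray(values, dtype=np.float64)
    qs = np.arange(1, 11) / 10.0
    thetas = np.quantile(arr, qs, method="linear")
    return ThresholdSet(thetas=thetas, measure_id=measure_id, source_n=arr.size)
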