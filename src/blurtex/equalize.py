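"""Recursive blur equalization.

The equalizing operator convolves an image with a small Gaussian step kernel
(default sigma = 1, 3x3) until an oriented blur measure reaches a threshold
theta.  Images already at or above theta are returned untouched, which makes
the operator idempotent.  Because all three built-in measures grow with
blur, the iteration normally terminates quickly; a ``max_iter`` cap keeps
near-constant images (which may never reach a high theta) from looping --
non-convergence is reported through a flag, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .image import Kernel2D, as_gray, convolve, gaussian_kernel
from .measures import BlurScore, DegenerateImageError, get_measure

__all__ = [
    "EqualizationResult",
    "equalize_blur",
    "equalize_schedule",
    "equalize_dataset",
    "ideal_equalize",
]


@dataclass
class EqualizationResult:
    """Outcome of equalizing one image.

    ``converged`` is true iff the final score reached theta within
    ``max_iter`` steps; ``iterations == 0`` iff the input already satisfied
    the stop test.  ``error`` carries the message when the measure was
    degenerate on the original image and the batch API was asked to collect
    rather than raise.
    """

    image: np.ndarray
    iterations: int
    final_score: BlurScore
    converged: bool
    error: str | None = None


def _step_kernel(step_sigma: float, step_size: int) -> Kernel2D:
    if step_sigma <= 0:
        raise ValueError("step_sigma must be positive")
    return gaussian_kernel(step_sigma, step_size)


def _blur_steps(image, measure_fn, kernel: Kernel2D, max_iter: int) -> Iterator[tuple[int, np.ndarray, float]]:
    """Yield ``(n, image_n, score_n)`` along the step-convolution trajectory."""
    cur = as_gray(image)
    for n in range(max_iter + 1):
        yield n, cur, measure_fn(cur).value
        if n < max_iter:
            cur = convolve(cur, kernel)


def equalize_blur(
    image,
    measure,
    theta: float,
    step_sigma: float = 1.0,
    step_size: int = 3,
    max_iter: int = 64,
) -> EqualizationResult:
    """Equalize one image to blur level ``theta``.

    Returns the image after the minimal number ``n >= 0`` of step-kernel
    convolutions such that the measure of the n-step image is >= theta.  If
    ``max_iter`` steps do not suffice, the ``max_iter``-step image is
    returned with ``converged=False``.

    A :class:`~blurtex.measures.DegenerateImageError` on the *original*
    image propagates with context -- such an image cannot be equalized.
    """
    mid, fn = get_measure(measure)
    kernel = _step_kernel(step_sigma, step_size)
    last = None
    try:
        for n, img, score in _blur_steps(image, fn, kernel, max_iter):
            last = (n, img, score)
            if score >= theta:
                return EqualizationResult(img, n, BlurScore(score, mid), True)
    except DegenerateImageError as exc:
        raise DegenerateImageError(
            f"image cannot be equalized with measure {mid!r}: {exc}"
        ) from exc
    n, img, score = last
    return EqualizationResult(img, n, BlurScore(score, mid), False)


def equalize_schedule(
    image,
    measure,
    thetas: Sequence[float],
    step_sigma: float = 1.0,
    step_size: int = 3,
    max_iter: int = 64,
) -> list[EqualizationResult]:
    """Equalize one image at several thresholds sharing a single trajectory.

    Equivalent to calling :func:`equalize_blur` once per theta (the score
    trajectory and stop tests are identical), but each step-convolution is
    performed only once.  Results are returned in the order of ``thetas``.
    """
    mid, fn = get_measure(measure)
    kernel = _step_kernel(step_sigma, step_size)
    order = np.argsort(np.asarray(thetas, dtype=np.float64), kind="stable")
    results: list[EqualizationResult | None] = [None] * len(order)
    pending = list(order)
    try:
        for n, img, score in _blur_steps(image, fn, kernel, max_iter):
            while pending and score >= thetas[pending[0]]:
                i = pending.pop(0)
                results[i] = EqualizationResult(img, n, BlurScore(score, mid), True)
            if not pending:
                break
        else:
            # ran out of iterations: remaining thresholds did not converge
            for i in pending:
                results[i] = EqualizationResult(img, n, BlurScore(score, mid), False)
    except DegenerateImageError as exc:
        raise DegenerateImageError(
            f"image cannot be equalized with measure {mid!r}: {exc}"
        ) from exc
    return results


def equalize_dataset(
    images: Sequence,
    measure,
    theta: float,
    step_sigma: float = 1.0,
    step_size: int = 3,
    max_iter: int = 64,
    on_error: str = "collect",
) -> list[EqualizationResult]:
    """Element-wise :func:`equalize_blur` with shared parameters.

    ``on_error="collect"`` records per-image degenerate-measure failures in
    the result's ``error`` field (the image passes through unmodified) so a
    batch never aborts silently; ``on_error="raise"`` propagates the first
    failure.
    """
    if len(images) == 0:
        raise ValueError("cannot equalize an empty dataset")
    if on_error not in ("collect", "raise"):
        raise ValueError("on_error must be 'collect' or 'raise'")
    mid, _ = get_measure(measure)
    out = []
    for img in images:
        try:
            out.append(
                equalize_blur(img, measure, theta, step_sigma, step_size, max_iter)
            )
        except DegenerateImageError as exc:
            if on_error == "raise":
                raise
            out.append(
                EqualizationResult(
                    as_gray(img), 0, BlurScore(float("nan"), mid), False, error=str(exc)
                )
            )
    return out


def ideal_equalize(image, current_sigma: float | None, target_sigma: float) -> np.ndarray:
    """Oracle equalization when the true Gaussian blur level is known.

    Uses the Gaussian semigroup: an image already blurred at
    ``current_sigma`` is brought to ``target_sigma`` by one convolution with
    a Gaussian of width sqrt(target^2 - current^2).  The operation only ever
    adds blur: targets at or below the current level leave the image
    unchanged (no deconvolution path exists).
    """
    if current_sigma is None:
        raise ValueError("ideal equalization requires the true Gaussian sigma")
    if current_sigma < 0 or target_sigma < 0:
        raise ValueError("sigma values must be nonnegative")
    img = as_gray(image)
    if target_sigma <= current_sigma:
        return img
    extra = float(np.sqrt(target_sigma**2 - current_sigma**2))
    return convolve(img, gaussian_kernel(extra))
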