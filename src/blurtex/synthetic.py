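"""Seeded generator of class-structured synthetic texture datasets.

Each class is an oriented band-pass noise process: white noise filtered in
the Fourier domain by a Gabor-like envelope centered on a class-specific
orientation and radial frequency (optionally with a second harmonic), plus a
small broadband noise floor.  The per-class contrast multiplier spreads the
intensity variation across classes the way a physical texture benchmark
mixes smooth, low-contrast surfaces with coarse, high-contrast ones -- that
spread is what gives the no-reference blur measures a wide dynamic range
over *sharp* images, which the decile thresholds of the equalization
framework rely on.

Everything is deterministic given the dataset seed; each patch draws from an
independent child generator keyed by (seed, class index, patch index), so
patches are independent and the dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TextureDataset
from .image import DegradationSpec, degrade

__all__ = [
    "ClassParams",
    "SyntheticDatasetSpec",
    "generate_dataset",
    "render_texture",
    "default_datasets",
    "make_degraded_copies",
    "gaussian_levels",
    "average_levels",
    "median_levels",
]


@dataclass(frozen=True)
class ClassParams:
    """Spectral recipe for one texture class.

    orientation : band orientation in radians (mod pi).
    frequency : radial center frequency in cycles/pixel (< 0.5).
    contrast : multiplier on the reference intensity std of 40 gray levels.
    rel_bandwidth : radial envelope sigma as a fraction of ``frequency``.
    angular_bandwidth : angular envelope sigma in radians.
    harmonic : relative amplitude of a second band at twice the frequency.
    """

    orientation: float
    frequency: float
    contrast: float = 1.0
    rel_bandwidth: float = 0.30
    angular_bandwidth: float = 0.25
    harmonic: float = 0.0


# Default eight-class mix: orientations spread over [0, pi), frequencies and
# contrasts spanning smooth/low-contrast to coarse/high-contrast surfaces.
_DEFAULT_FREQS = (0.040, 0.280, 0.055, 0.200, 0.120, 0.320, 0.050, 0.240)
_DEFAULT_CONTRASTS = (0.25, 1.40, 0.19, 1.00, 0.60, 1.20, 0.225, 0.80)
_DEFAULT_HARMONICS = (0.0, 0.0, 0.0, 0.40, 0.30, 0.0, 0.0, 0.0)


def default_class_params(n_classes: int) -> tuple[ClassParams, ...]:
    params = []
    for c in range(n_classes):
        f = _DEFAULT_FREQS[c % len(_DEFAULT_FREQS)]
        harm = _DEFAULT_HARMONICS[c % len(_DEFAULT_HARMONICS)]
        if 2.0 * f > 0.45:  # keep harmonics below Nyquist with margin
            harm = 0.0
        params.append(
            ClassParams(
                orientation=np.pi * c / n_classes,
                frequency=f,
                contrast=_DEFAULT_CONTRASTS[c % len(_DEFAULT_CONTRASTS)],
                harmonic=harm,
            )
        )
    return tuple(params)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Shape and recipe of a generated dataset (fully seeded)."""

    n_classes: int = 8
    n_per_class: int = 20
    patch_size: int = 128
    seed: int = 7
    noise_floor: float = 0.06  # broadband noise relative to the band-pass std
    class_params: tuple[ClassParams, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.class_params is None:
            object.__setattr__(self, "class_params", default_class_params(self.n_classes))
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.patch_size < 64:
            raise ValueError("patch_size must be at least 64")
        if len(self.class_params) != self.n_classes:
            raise ValueError("class_params length must equal n_classes")
        _check_distinctness(self.class_params)


def _angdist(a: float, b: float) -> float:
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def _check_distinctness(params) -> None:
    """Classes must differ in orientation or frequency by a stated margin."""
    n = len(params)
    ang_margin = np.pi / (2 * n)
    for i in range(n):
        for j in range(i + 1, n):
            pi_, pj = params[i], params[j]
            dfreq = abs(pi_.frequency - pj.frequency) / min(pi_.frequency, pj.frequency)
            if _angdist(pi_.orientation, pj.orientation) < ang_margin and dfreq < 0.2:
                raise ValueError(
                    f"classes {i} and {j} violate the distinctness margin "
                    f"(orientation and frequency both too close)"
                )


def _band_envelope(size: int, p: ClassParams) -> np.ndarray:
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    ang = np.arctan2(fy, fx)
    dang = np.abs(ang - p.orientation) % np.pi
    dang = np.minimum(dang, np.pi - dang)
    angular = np.exp(-(dang**2) / (2.0 * p.angular_bandwidth**2))
    radial = np.exp(-((f - p.frequency) ** 2) / (2.0 * (p.rel_bandwidth * p.frequency) ** 2))
    env = radial * angular
    if p.harmonic > 0:
        radial2 = np.exp(
            -((f - 2.0 * p.frequency) ** 2)
            / (2.0 * (p.rel_bandwidth * 2.0 * p.frequency) ** 2)
        )
        env = env + p.harmonic * radial2 * angular
    env[0, 0] = 0.0  # no DC
    return env


def _patch(rng: np.random.Generator, size: int, p: ClassParams, noise_floor: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    band = np.fft.ifft2(np.fft.fft2(noise) * _band_envelope(size, p)).real
    band /= band.std()
    tex = band + noise_floor * rng.standard_normal((size, size))
    tex = (tex - tex.mean()) / tex.std()
    return np.clip(127.0 + 40.0 * p.contrast * tex, 0.0, 255.0)


def render_texture(
    params: ClassParams, size: int = 128, seed: int = 0, noise_floor: float = 0.06
) -> np.ndarray:
    """One seeded texture patch from a single class recipe."""
    return _patch(np.random.default_rng(seed), size, params, noise_floor)


def generate_dataset(spec: SyntheticDatasetSpec) -> TextureDataset:
    """Generate a labeled dataset from a :class:`SyntheticDatasetSpec`."""
    images, labels = [], []
    for c, p in enumerate(spec.class_params):
        for i in range(spec.n_per_class):
            rng = np.random.default_rng([spec.seed, c, i])
            images.append(_patch(rng, spec.patch_size, p, spec.noise_floor))
            labels.append(c)
    names = [f"class{c:02d}" for c in range(spec.n_classes)]
    return TextureDataset(images, np.asarray(labels), names, meta={"spec": spec})


def default_datasets(seed: int = 7, n_per_class: int = 20, **kwargs):
    """The frozen study layout: a clean training set "A" and a separate
    evaluation set "B" with the same class recipes but independent noise.

    Returns ``(train, eval)``; degradations are applied only to copies of the
    evaluation set (see :func:`make_degraded_copies`).
    """
    train = generate_dataset(
        SyntheticDatasetSpec(n_per_class=n_per_class, seed=seed, **kwargs)
    )
    evaluation = generate_dataset(
        SyntheticDatasetSpec(n_per_class=n_per_class, seed=seed + 1_000_003, **kwargs)
    )
    return train, evaluation


def gaussian_levels(max_sigma: float = 4.0, step: float = 0.5) -> list[DegradationSpec]:
    """The nine Gaussian blur levels sigma = 0, 0.5, ..., 4 (sigma=0 is identity)."""
    sigmas = np.arange(0.0, max_sigma + step / 2, step)
    return [DegradationSpec("gaussian", sigma=float(s)) for s in sigmas]


def average_levels(max_size: int = 9) -> list[DegradationSpec]:
    """Averaging filters of size 1x1 (unfiltered) through ``max_size``."""
    return [DegradationSpec("average", size=s) for s in range(1, max_size + 1, 2)]


def median_levels(max_size: int = 9) -> list[DegradationSpec]:
    """Median filters of size 1x1 (unfiltered) through ``max_size``."""
    return [DegradationSpec("median", size=s) for s in range(1, max_size + 1, 2)]


def make_degraded_copies(dataset: TextureDataset, specs) -> dict:
    """Degraded copies of a dataset, one per spec, keyed by the spec's label.

    Labels and image order (hence pairing with the originals) are preserved;
    identity specs return bit-identical copies.  Each copy records the
    applied :class:`DegradationSpec` under ``meta["degradation"]``.
    """
    out = {}
    for spec in specs:
        copy = dataset.map_images(lambda img, s=spec: degrade(img, s))
        copy.meta["degradation"] = spec
        out[spec.label] = copy
    return out
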