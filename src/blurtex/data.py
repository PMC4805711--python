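"""Labeled image collections and Kylberg-style directory trees.

A dataset is a flat list of grayscale images with integer labels and class
names.  On disk the layout is one directory per class containing raster
images (PNG/TIFF/PGM), which is the layout texture benchmarks such as
Kylberg use; any tree of that shape is accepted interchangeably with the
built-in synthetic generator's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import load_image, save_image

__all__ = ["TextureDataset", "load_dataset", "save_dataset"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".pgm", ".ppm", ".bmp", ".jpg", ".jpeg"}


@dataclass
class TextureDataset:
    """Images with integer class labels.

    ``labels[i]`` indexes into ``class_names``.  ``meta`` carries optional
    per-image ground truth (e.g. the true Gaussian sigma of a simulated
    degradation) keyed by name.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != self.labels.size:
            raise ValueError("images and labels must have the same length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def map_images(self, fn) -> "TextureDataset":
        """Apply ``fn`` to every image, preserving labels and metadata."""
        return TextureDataset(
            [fn(img) for img in self.images],
            self.labels.copy(),
            list(self.class_names),
            dict(self.meta),
        )


def load_dataset(root) -> TextureDataset:
    """Load a directory-per-class tree of raster images (sorted, deterministic)."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    images, labels, class_names = [], [], []
    for ci, cdir in enumerate(class_dirs):
        class_names.append(cdir.name)
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        for f in files:
            images.append(load_image(f))
            labels.append(ci)
    if not images:
        raise ValueError(f"no images found under {root}")
    return TextureDataset(images, np.asarray(labels), class_names)


def save_dataset(dataset: TextureDataset, root, manifest: str | None = "manifest.csv") -> None:
    """Write a dataset as a directory-per-class PNG tree plus a manifest CSV."""
    import csv

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    counters = {name: 0 for name in dataset.class_names}
    rows = []
    for img, lab in zip(dataset.images, dataset.labels):
        cname = dataset.class_names[lab]
        cdir = root / cname
        cdir.mkdir(exist_ok=True)
        idx = counters[cname]
        counters[cname] += 1
        path = cdir / f"{cname}_{idx:04d}.png"
        save_image(path, img)
        rows.append((str(path.relative_to(root)), cname))
    if manifest:
        with open(root / manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "class"])
            writer.writerows(rows)
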