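"""Labeled grayscale image collections and their on-disk layout.

An :class:`ImageDataset` holds a stack of same-sized grayscale images in
``[0, 1]``, integer class labels, the class-name table, and a per-image
provenance tag (``"original"`` for collected/synthesized source images,
``"generated"`` for GAN output).  On disk a dataset is one subdirectory of
8-bit PNGs per class plus a ``manifest.csv`` (path, class, provenance, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["CLASS_NAMES", "ImageDataset"]

#: The four bladder-mucosa classes, in fixed label order.
CLASS_NAMES = ("non_cancer", "high_grade", "low_grade", "cis")


@dataclass
class ImageDataset:
    """Stack of grayscale images with labels and provenance.

    Attributes
    ----------
    images : float array, shape (n, h, w), values in [0, 1].
    labels : int array, shape (n,), indices into ``class_names``.
    class_names : ordered class-name tuple.
    provenance : str array, shape (n,), "original" or "generated".
    seeds : int array, shape (n,), the per-image generation seed (-1 if n/a).
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: Sequence[str] = CLASS_NAMES
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    seeds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            self.images = self.images.reshape((len(self.labels), 0, 0))
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), "original", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.seeds is None:
            self.seeds = np.full(len(self.labels), -1, dtype=np.int64)
        else:
            self.seeds = np.asarray(self.seeds, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def image_size(self) -> int:
        return self.images.shape[1] if len(self) else 0

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        """Per-class image counts in label order."""
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "ImageDataset":
        indices = np.asarray(indices)
        return ImageDataset(
            self.images[indices],
            self.labels[indices],
            self.class_names,
            self.provenance[indices],
            self.seeds[indices],
        )

    @staticmethod
    def concatenate(parts: Sequence["ImageDataset"]) -> "ImageDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("nothing to concatenate")
        names = parts[0].class_names
        if any(tuple(p.class_names) != tuple(names) for p in parts):
            raise ValueError("class-name tables differ")
        return ImageDataset(
            np.concatenate([p.images for p in parts]),
            np.concatenate([p.labels for p in parts]),
            names,
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.seeds for p in parts]),
        )

    # ------------------------------------------------------------------ IO
    def save(self, root: str | Path) -> Path:
        """Write one PNG per image under per-class subdirectories + manifest."""
        root = Path(root)
        rows = []
        counters = {name: 0 for name in self.class_names}
        for i in range(len(self)):
            name = self.class_names[self.labels[i]]
            counters[name] += 1
            rel = Path(name) / f"{name}_{counters[name]:05d}.png"
            path = root / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            arr = np.clip(np.round(self.images[i] * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
            rows.append(
                {
                    "path": str(rel),
                    "class": name,
                    "provenance": self.provenance[i],
                    "seed": int(self.seeds[i]),
                }
            )
        manifest = root / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @staticmethod
    def load(root: str | Path, class_names: Sequence[str] = CLASS_NAMES) -> "ImageDataset":
        """Read a dataset previously written by :meth:`save`."""
        root = Path(root)
        manifest = pd.read_csv(root / "manifest.csv")
        images, labels, prov, seeds = [], [], [], []
        index = {name: i for i, name in enumerate(class_names)}
        for rec in manifest.to_dict("records"):
            arr = np.asarray(Image.open(root / rec["path"]), dtype=np.float32) / 255.0
            images.append(arr)
            labels.append(index[rec["class"]])
            prov.append(rec["provenance"])
            seeds.append(rec["seed"])
        return ImageDataset(
            np.stack(images), np.array(labels), class_names, np.array(prov, dtype=object), np.array(seeds)
        )
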