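"""Labeled datasets and their on-disk formats.

A :class:`LabeledDataset` is the input side of the information channel: real
feature vectors in [-1, 1] with one integer class label per sample.  Two disk
formats are supported: plain CSV (one sample per row, label in the last
column) and the MNIST IDX binary format, with pixel values rescaled to
[-1, 1] on load.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "load_csv_dataset",
    "save_csv_dataset",
    "load_idx_images",
    "load_idx_labels",
    "load_idx_dataset",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


@dataclass
class LabeledDataset:
    """Feature vectors with integer class labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Real-valued features, expected in [-1, 1].
    labels : ndarray of shape (n_samples,)
        Integer class labels in ``{0, ..., n_classes - 1}``.
    n_classes : int
        Number of classes C (>= 2).  Defaults to ``labels.max() + 1``.
    """

    features: np.ndarray
    labels: np.ndarray
    n_classes: int = field(default=0)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"feature rows ({self.features.shape[0]}) != "
                f"label count ({self.labels.shape[0]})"
            )
        if self.n_classes == 0:
            self.n_classes = int(self.labels.max()) + 1 if self.labels.size else 2
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels must lie in {0..n_classes-1}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.features[idx], self.labels[idx], self.n_classes)


def load_csv_dataset(path: str | Path, n_classes: int | None = None) -> LabeledDataset:
    """Read a dataset from CSV: one sample per row, integer label in the last column."""
    frame = pd.read_csv(path, header=None)
    features = frame.iloc[:, :-1].to_numpy(dtype=float)
    labels = frame.iloc[:, -1].to_numpy(dtype=int)
    return LabeledDataset(features, labels, n_classes or 0)


def save_csv_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    out = np.column_stack([dataset.features, dataset.labels.astype(float)])
    frame = pd.DataFrame(out)
    frame[frame.columns[-1]] = frame[frame.columns[-1]].astype(int)
    frame.to_csv(path, header=False, index=False)


def _read_idx_header(fh, expected_magic: int, n_dims: int) -> tuple[int, ...]:
    magic = struct.unpack(">I", fh.read(4))[0]
    if magic != expected_magic:
        raise ValueError(f"bad IDX magic 0x{magic:08x}, expected 0x{expected_magic:08x}")
    return struct.unpack(f">{n_dims}I", fh.read(4 * n_dims))


def load_idx_images(path: str | Path) -> np.ndarray:
    """Read an IDX image file (magic 0x00000803) and rescale pixels to [-1, 1]."""
    with open(path, "rb") as fh:
        n, rows, cols = _read_idx_header(fh, _IDX_IMAGE_MAGIC, 3)
        raw = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    pixels = raw.reshape(n, rows * cols).astype(float)
    return pixels / 127.5 - 1.0


def load_idx_labels(path: str | Path) -> np.ndarray:
    """Read an IDX label file (magic 0x00000801)."""
    with open(path, "rb") as fh:
        (n,) = _read_idx_header(fh, _IDX_LABEL_MAGIC, 1)
        raw = np.frombuffer(fh.read(n), dtype=np.uint8)
    return raw.astype(int)


def load_idx_dataset(
    image_path: str | Path, label_path: str | Path, n_classes: int = 10
) -> LabeledDataset:
    return LabeledDataset(load_idx_images(image_path), load_idx_labels(label_path), n_classes)
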