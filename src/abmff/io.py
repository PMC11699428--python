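"""8-bit grayscale image I/O (PNG/TIFF/PGM) and label-map sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "write_labels", "read_labels"]


def read_gray(path) -> np.ndarray:
    """Read a single-channel 8-bit grayscale image.

    Multi-channel inputs are rejected rather than silently converted: the
    method is defined on the 256 grayscale states only.
    """
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel grayscale, got shape {img.shape}")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError(f"{path}: intensities outside [0, 255]")
        img = img.astype(np.uint8)
    return img


def write_gray(path, image: np.ndarray) -> None:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    iio.imwrite(path, img.astype(np.uint8))


def _label_levels(k: int) -> np.ndarray:
    # distinct, evenly spread gray levels for labels 1..k
    return np.round(np.linspace(0, 255, k)).astype(np.uint8) if k > 1 \
        else np.array([255], dtype=np.uint8)


def write_labels(path, labels: np.ndarray, sidecar: dict | None = None) -> None:
    """Write a label image as PNG (labels mapped to spread gray levels).

    A JSON sidecar (same path + ``.json``) records the label->gray mapping
    plus any extra metadata (centroids, k, seed, ...), so the PNG can be
    decoded back to labels exactly.
    """
    lab = np.asarray(labels)
    k = int(lab.max())
    if lab.min() < 1:
        raise ValueError("labels must be >= 1")
    levels = _label_levels(k)
    iio.imwrite(path, levels[lab - 1])
    meta = {"k": k, "gray_levels": levels.tolist()}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_labels(path) -> np.ndarray:
    """Decode a label PNG written by :func:`write_labels` back to labels 1..k."""
    meta = json.loads(Path(str(path) + ".json").read_text())
    levels = np.asarray(meta["gray_levels"], dtype=np.uint8)
    img = read_gray(path)
    lut = np.zeros(256, dtype=np.int32)
    lut[levels] = np.arange(1, levels.size + 1)
    labels = lut[img]
    if np.any(labels == 0):
        raise ValueError(f"{path}: gray level not present in sidecar mapping")
    return labels
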