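"""Reading and writing images, label maps and truth sidecars.

Images go through ``tifffile`` (multi-page for stacks and series); truth
sidecars are written as ``<stem>.truth.json`` with the per-nucleus label
map, when present, stored losslessly as ``<stem>.labels.tif`` (16-bit).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .synthetic import GroundTruth

__all__ = [
    "write_image",
    "write_stack",
    "read_image",
    "read_stack",
    "write_truth",
    "write_labels",
]


def write_image(path: str | Path, image: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def write_stack(path: str | Path, stack: np.ndarray) -> Path:
    """Write a 3D array as a multi-page TIFF (one page per plane)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError(f"expected a multi-page stack, got shape {arr.shape}")
    return arr


def write_labels(path: str | Path, label_map: np.ndarray) -> Path:
    if label_map.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label map")
    path = Path(path)
    tifffile.imwrite(path, label_map.astype(np.uint16))
    return path


def write_truth(stem: str | Path, truth: GroundTruth) -> Path:
    """Write ``<stem>.truth.json`` (+ ``<stem>.labels.tif`` if masks exist)."""
    stem = Path(stem)
    json_path = stem.with_suffix(stem.suffix + ".truth.json") if stem.suffix else Path(
        str(stem) + ".truth.json"
    )
    json_path.write_text(truth.to_json() + "\n")
    if truth.label_map is not None and truth.label_map.max() > 0:
        write_labels(Path(str(stem) + ".labels.tif"), truth.label_map)
    return json_path
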