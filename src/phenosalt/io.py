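"""File-format plumbing: PNG/TIFF images, colour references, CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .segmentation import LabelMask, NearestColorClassifier, train_color_classifier

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_color_reference",
    "write_color_reference",
    "parse_image_name",
]

#: Canonical view names and the file naming convention
#: ``<plantID>_day<D>_<view>.png`` used by the pipeline commands.
RGB_VIEWS = ("side1", "side2", "top")
ALL_VIEWS = RGB_VIEWS + ("fluor",)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF), dropping any alpha channel."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_color_reference(
    path: str | Path, samples: Iterable[tuple[tuple[int, int, int], str]]
) -> None:
    """Persist (RGB, label) classifier training samples as CSV."""
    rows = [(lab, r, g, b) for (r, g, b), lab in samples]
    pd.DataFrame(rows, columns=["label", "r", "g", "b"]).to_csv(path, index=False)


def read_color_reference(
    path: str | Path, tie_priority: list[str] | None = None
) -> NearestColorClassifier:
    """Train a colour classifier from a reference CSV (label,r,g,b)."""
    df = pd.read_csv(path)
    samples = [
        ((int(row.r), int(row.g), int(row.b)), str(row.label))
        for row in df.itertuples()
    ]
    return train_color_classifier(samples, tie_priority=tie_priority)


def parse_image_name(name: str) -> tuple[str, int, str]:
    """Split ``plantID_day<D>_<view>.<ext>`` into (plant_id, day, view)."""
    stem = Path(name).stem
    parts = stem.rsplit("_", 2)
    if len(parts) != 3 or not parts[1].startswith("day") or parts[2] not in ALL_VIEWS:
        raise ValueError(
            f"image name {name!r} does not follow <plantID>_day<D>_<view>"
        )
    try:
        day = int(parts[1][3:])
    except ValueError as exc:
        raise ValueError(f"bad day field in {name!r}") from exc
    return parts[0], day, parts[2]
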