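"""Image, mask, tip-table and report input/output.

Images are PNG or TIFF, 8/16-bit grayscale or RGB; internally everything is
a float array normalized to [0, 1].  Masks are single-channel PNGs with 0 =
background and any nonzero value = foreground.  Leaf-tip tables are CSVs
with header ``row,col``.  Evaluation reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

# Rec. 709 luminance weights for RGB -> gray
_LUMA = np.array([0.2126, 0.7152, 0.0722])

REPORT_KEYS = (
    "sdi",
    "tip_distance_mean",
    "tip_distance_std",
    "breakages",
    "n_control_points",
    "stop_reason_counts",
)


def _dtype_scale(arr: np.ndarray) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return 1.0
    return float(max(arr.max(), 1))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a float grayscale array in [0, 1].

    RGB(A) input is converted to luminance (0.2126 R + 0.7152 G + 0.0722 B);
    the alpha channel, if present, is discarded.
    """
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path}")
    scale = _dtype_scale(arr)
    arr = arr.astype(np.float64) / scale
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected 2D or RGB image, got shape {arr.shape}")
    return np.clip(arr, 0.0, 1.0)


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a single-channel mask PNG; nonzero pixels become True.

    If ``shape`` is given, a dimension mismatch raises ``ValueError``.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate RGB-saved masks
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel, got shape {arr.shape}")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match expected {tuple(shape)}")
    return arr != 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def load_labels(path: str | Path) -> np.ndarray:
    """Read a labeled-leaf mask (16-bit PNG of integer labels)."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError("label mask must be single-channel")
    return arr.astype(np.int32)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, labels.astype(np.uint16))


def load_tips(path: str | Path) -> np.ndarray:
    """Read a leaf-tip table (CSV with header row,col) as an (n, 2) array."""
    df = pd.read_csv(path)
    if not {"row", "col"} <= set(df.columns):
        raise ValueError("tips CSV must have columns row,col")
    return df[["row", "col"]].to_numpy(float)


def write_tips(tips: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(tips, float), columns=["row", "col"]).to_csv(
        path, index=False
    )


def write_report(metrics: dict, path: str | Path) -> None:
    """Write an evaluation report as JSON.

    Absent metrics are recorded as null so the key set is stable.
    """
    payload = {k: metrics.get(k) for k in REPORT_KEYS}
    payload.update({k: v for k, v in metrics.items() if k not in REPORT_KEYS})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
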