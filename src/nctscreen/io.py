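"""Standard-format I/O: single-channel grayscale TIFFs and CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


def field_filename(plate: str, well: str, field_idx: int, channel: str) -> str:
    return f"{plate}_{well}_{field_idx}_{channel}.tif"


def write_field_tiffs(field, out_dir, *, plate: str = "P1", well: str = "A01",
                      field_idx: int = 0) -> list[Path]:
    """Write each channel of a field as one grayscale TIFF.

    Float rasters are rounded and cast to the bit depth of the
    simulation parameters (8 or 16 bit).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bit_depth = getattr(getattr(field, "params", None), "bit_depth", 16)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    maxv = 2 ** bit_depth - 1
    paths = []
    for name, img in field.channels.items():
        path = out_dir / field_filename(plate, well, field_idx, name)
        tifffile.imwrite(path, np.clip(np.round(img), 0, maxv).astype(dtype))
        paths.append(path)
    return paths


def read_channel_tiff(path) -> np.ndarray:
    """Read a single-channel grayscale TIFF as float64."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image")
    return img.astype(float)


def write_label_tiff(label_mask: np.ndarray, path) -> Path:
    """Write a label mask as 16-bit TIFF."""
    path = Path(path)
    if label_mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(path, label_mask.astype(np.uint16))
    return path
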