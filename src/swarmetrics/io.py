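"""File formats: single-channel TIFF rasters, 16-bit label TIFF, CSV tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import LabelImage, RasterImage


def read_image(path, pixel_size: float) -> RasterImage:
    """Read a single-channel TIFF as a float raster with the given pixel size (µm/px)."""
    px = tifffile.imread(str(path))
    if px.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D TIFF, got shape {px.shape}")
    return RasterImage(px.astype(np.float64), pixel_size)


def write_image(path, image: RasterImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_label_image(path, pixel_size: float) -> LabelImage:
    lab = tifffile.imread(str(path))
    if lab.ndim != 2:
        raise ValueError(f"{path}: expected a 2D label TIFF, got shape {lab.shape}")
    return LabelImage(lab.astype(np.int32), pixel_size)


def write_label_image(path, labels: LabelImage) -> None:
    lab = labels.labels
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit label TIFF")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def write_cells_csv(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def crop_region(image: RasterImage, rect: tuple[int, int, int, int]) -> RasterImage:
    """Crop a rectangular region (row0, col0, height, width), preserving pixel size.

    Used to excise layered, oversaturated or out-of-focus regions before
    analysis. The rectangle must lie fully inside the image.
    """
    r0, c0, rh, cw = (int(v) for v in rect)
    h, w = image.shape
    if rh <= 0 or cw <= 0:
        raise ValueError("crop rectangle must have positive size")
    if r0 < 0 or c0 < 0 or r0 + rh > h or c0 + cw > w:
        raise ValueError(f"crop rectangle {rect} outside image of shape {(h, w)}")
    return RasterImage(image.pixels[r0 : r0 + rh, c0 : c0 + cw].copy(), image.pixel_size)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
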