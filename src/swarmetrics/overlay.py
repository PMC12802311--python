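"""Pseudo-color overlays of segmented cells on the phase image.

``length_type`` mode fills SHORT cells (≤ 4 µm) green and LONG cells
(> 4 µm) blue — the conventional coloring for swarm subpopulations;
``outline`` mode draws particle contours in yellow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage.segmentation import find_boundaries

from .morphometry import LONG
from .types import LabelImage, RasterImage

SHORT_COLOR = (0, 200, 0)  # green
LONG_COLOR = (40, 90, 255)  # blue
OUTLINE_COLOR = (255, 220, 0)  # yellow


def _to_rgb_base(phase: RasterImage) -> np.ndarray:
    px = phase.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    gray = (scaled * 255).astype(np.uint8)
    return np.stack([gray] * 3, axis=2)


def render_overlay(
    phase: RasterImage,
    records: pd.DataFrame,
    labels: LabelImage,
    mode: str = "length_type",
    path=None,
    alpha: float = 0.6,
) -> np.ndarray:
    """Render an RGB overlay; optionally save it to ``path`` (PNG).

    With an empty record table the base image is returned unmodified. Only
    particles present in ``records`` are drawn, so filtered-out debris stays
    uncolored.
    """
    if mode not in ("outline", "length_type"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    if phase.shape != labels.shape:
        raise ValueError("phase and label rasters are not aligned")
    rgb = _to_rgb_base(phase)
    if not records.empty:
        lab = labels.labels
        if mode == "length_type":
            short_ids = records.loc[records["type"] != LONG, "id"].to_numpy()
            long_ids = records.loc[records["type"] == LONG, "id"].to_numpy()
            for ids, color in ((short_ids, SHORT_COLOR), (long_ids, LONG_COLOR)):
                if ids.size == 0:
                    continue
                m = np.isin(lab, ids)
                for ch in range(3):
                    rgb[:, :, ch] = np.where(
                        m,
                        ((1 - alpha) * rgb[:, :, ch] + alpha * color[ch]).astype(np.uint8),
                        rgb[:, :, ch],
                    )
        else:
            keep = np.isin(lab, records["id"].to_numpy())
            edges = find_boundaries(np.where(keep, lab, 0), mode="inner")
            for ch in range(3):
                rgb[:, :, ch] = np.where(edges, OUTLINE_COLOR[ch], rgb[:, :, ch])
    if path is not None:
        iio.imwrite(str(path), rgb)
    return rgb
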