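"""Per-cell fluorescence quantification with cell-free background normalization.

Background autofluorescence is estimated per frame by averaging the mean
intensity of square boxes (default four 5×5 µm boxes) placed uniformly at
random on cell-free areas — "cell-free" meaning no labeled pixel inside the
box, which is reproducible and auditable. Each cell's mean fluorescence is
then the mean of (fluorescence − background) over its pixels; values below
background stay negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import LabelImage, RasterImage


class BackgroundError(RuntimeError):
    """Raised when the requested number of cell-free boxes cannot be placed."""


@dataclass
class BackgroundEstimate:
    """Audit record of one background estimation."""

    box_size_um: float
    n_boxes: int
    box_positions_um: list  # (row, col) of each box's top-left corner, µm
    box_means: list  # per-box mean intensity, a.u.
    mean_background: float  # arithmetic mean of the box means, a.u.
    seed: int
    overlap_allowed: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "box_size_um": self.box_size_um,
                "n_boxes": self.n_boxes,
                "box_positions_um": [list(map(float, p)) for p in self.box_positions_um],
                "box_means": [float(m) for m in self.box_means],
                "mean_background": float(self.mean_background),
                "seed": self.seed,
                "overlap_allowed": self.overlap_allowed,
            },
            indent=2,
        )


def _check_aligned(fluor: RasterImage, labels: LabelImage) -> None:
    if fluor.shape != labels.shape:
        raise ValueError(f"raster shapes differ: {fluor.shape} vs {labels.shape}")
    if not np.isclose(fluor.pixel_size, labels.pixel_size):
        raise ValueError("fluorescence and label rasters have different pixel sizes")


def estimate_background(
    fluor: RasterImage,
    labels: LabelImage,
    box_size_um: float = 5.0,
    n_boxes: int = 4,
    seed: int = 0,
) -> BackgroundEstimate:
    """Estimate background from randomly placed cell-free boxes.

    Candidate positions are all box placements fully inside the image whose
    pixels contain no label; boxes are drawn without replacement, preferring
    non-overlapping placements (overlap is allowed, and flagged in the audit
    record, only if non-overlapping placement fails). Raises
    :class:`BackgroundError` if fewer than ``n_boxes`` cell-free positions
    exist — boxes are never silently shrunk.
    """
    _check_aligned(fluor, labels)
    ps = fluor.pixel_size
    b = int(round(box_size_um / ps))
    if b < 1:
        raise ValueError("box size is below one pixel")
    h, w = fluor.shape
    if b > h or b > w:
        raise BackgroundError("box does not fit inside the image")
    occupied = (labels.labels > 0).astype(np.float64)
    # windowed occupancy count via cumulative sums; valid top-left corners
    # are those whose b×b window contains zero labeled pixels
    csum = np.cumsum(np.cumsum(occupied, axis=0), axis=1)
    padded = np.zeros((h + 1, w + 1))
    padded[1:, 1:] = csum
    win = (
        padded[b:, b:] - padded[:-b, b:] - padded[b:, :-b] + padded[:-b, :-b]
    )  # (h-b+1, w-b+1)
    free_r, free_c = np.nonzero(win == 0)
    if free_r.size < n_boxes:
        raise BackgroundError(
            f"only {free_r.size} cell-free {box_size_um}×{box_size_um} µm box "
            f"positions available, need {n_boxes}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(free_r.size)
    chosen: list[tuple[int, int]] = []
    overlap_allowed = False
    for i in perm:  # greedy non-overlapping pass
        r, c = int(free_r[i]), int(free_c[i])
        if all(abs(r - r2) >= b or abs(c - c2) >= b for r2, c2 in chosen):
            chosen.append((r, c))
        if len(chosen) == n_boxes:
            break
    if len(chosen) < n_boxes:
        overlap_allowed = True
        taken = set(chosen)
        for i in perm:
            r, c = int(free_r[i]), int(free_c[i])
            if (r, c) not in taken:
                chosen.append((r, c))
                taken.add((r, c))
            if len(chosen) == n_boxes:
                break
    means = [float(fluor.pixels[r : r + b, c : c + b].mean()) for r, c in chosen]
    return BackgroundEstimate(
        box_size_um=box_size_um,
        n_boxes=n_boxes,
        box_positions_um=[(r * ps, c * ps) for r, c in chosen],
        box_means=means,
        mean_background=float(np.mean(means)),
        seed=seed,
        overlap_allowed=overlap_allowed,
    )


def measure_intensity(
    fluor: RasterImage,
    labels: LabelImage,
    background: BackgroundEstimate,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Set each record's mean_intensity_au to mean(fluorescence − background) over its pixels.

    Negative values (cells dimmer than background) are preserved. Raises
    ``KeyError`` if a record id is absent from the label raster.
    """
    _check_aligned(fluor, labels)
    ids = records["id"].to_numpy()
    present = set(np.unique(labels.labels).tolist())
    missing = [int(i) for i in ids if int(i) not in present]
    if missing:
        raise KeyError(f"labels absent from raster: {missing[:10]}")
    if ids.size:
        means = ndimage.mean(
            fluor.pixels - background.mean_background, labels=labels.labels, index=ids
        )
    else:
        means = []
    out = records.copy()
    out["mean_intensity_au"] = np.asarray(means, dtype=float)
    return out
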