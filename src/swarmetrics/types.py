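"""Shared raster carriers: grayscale images and label images with physical pixel size."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RasterImage:
    """A 2D grayscale raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensities in arbitrary units. Must be finite.
    pixel_size : float
        Physical edge length of one pixel in µm/px. Must be positive.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("raster contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelImage:
    """Integer-labeled connected components over a binary mask.

    Label 0 is background; positive labels identify particles. Carries the
    same physical pixel size as the raster it was derived from.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected a 2D label raster, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive labels present in the raster."""
        u = np.unique(self.labels)
        return u[u > 0]
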