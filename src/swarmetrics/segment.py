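"""Trainable three-class pixel classification and mask post-processing.

The classifier separates CELL, BACKGROUND and INTERSPACE (the thin bright
seams between touching cells plus flagella-like clutter) from a small bank
of per-pixel convolutional features, mirroring the trainable-segmentation
approach common in bioimage analysis: sparse manual strokes train a random
forest, which then produces per-class probability maps; thresholding the
CELL probability yields binary masks. The third class exists only to absorb
seams and clutter — it is discarded at binarization, which is what makes
touching cells separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .types import RasterImage

FEATURE_VERSION = 1
DEFAULT_SIGMA_LADDER = (1.0, 2.0, 4.0, 8.0)


class PixelClass(IntEnum):
    CELL = 1
    BACKGROUND = 2
    INTERSPACE = 3


class TrainingError(ValueError):
    """Raised when annotations are unusable for training."""


@dataclass
class AnnotationSet:
    """Sparse pixel labels over one image.

    Coordinates are 0-based (row, col); classes are :class:`PixelClass`
    values. Each pixel may be labeled at most once.
    """

    image_ref: str
    rows: np.ndarray
    cols: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if not (self.rows.shape == self.cols.shape == self.classes.shape):
            raise ValueError("rows, cols and classes must have identical shapes")
        coords = np.stack([self.rows, self.cols], axis=1)
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("a pixel is labeled more than once")
        bad = set(np.unique(self.classes)) - {int(c) for c in PixelClass}
        if bad:
            raise ValueError(f"unknown annotation classes: {sorted(bad)}")

    @classmethod
    def from_label_raster(cls, raster: np.ndarray, image_ref: str = "") -> "AnnotationSet":
        """Build from a label raster (0 = unlabeled, 1 = cell, 2 = background, 3 = interspace)."""
        rr, cc = np.nonzero(raster)
        return cls(image_ref=image_ref, rows=rr, cols=cc, classes=raster[rr, cc])

    def to_label_raster(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.uint8)
        out[self.rows, self.cols] = self.classes
        return out

    def present_classes(self) -> set[PixelClass]:
        return {PixelClass(int(c)) for c in np.unique(self.classes)}


@dataclass
class FeatureStack:
    """Per-pixel feature vectors for one image; order is fixed and versioned."""

    data: np.ndarray  # (H, W, F) float32
    names: tuple[str, ...]
    sigma_ladder: tuple[float, ...]
    version: int = FEATURE_VERSION

    def as_matrix(self) -> np.ndarray:
        return self.data.reshape(-1, self.data.shape[2])


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, ordered (CELL, BACKGROUND, INTERSPACE)."""

    probabilities: np.ndarray  # (H, W, 3)
    pixel_size: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) probabilities, got {p.shape}")
        if p.min() < -1e-9:
            raise ValueError("negative class probability")
        sums = p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("class probabilities do not sum to 1 within 1e-6")
        self.probabilities = p

    def p(self, cls: PixelClass) -> np.ndarray:
        return self.probabilities[:, :, int(cls) - 1]


def compute_features(
    image: RasterImage, sigma_ladder: tuple[float, ...] = DEFAULT_SIGMA_LADDER
) -> FeatureStack:
    """Per-pixel feature bank: Gaussian ladder + gradient magnitude + Laplacian + DoG.

    A sigma of 0 contributes only the identity smoothing feature (the raw
    image); derivative features are computed for positive sigmas. On a
    constant image all derivative features are exactly zero and all
    smoothing features equal the constant.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.size == 0:
        raise ValueError("cannot compute features of an empty image")
    sigmas = tuple(float(s) for s in sigma_ladder)
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be non-negative")
    if list(sigmas) != sorted(sigmas):
        raise ValueError("sigma ladder must be sorted ascending")

    feats: list[np.ndarray] = []
    names: list[str] = []
    smoothed: dict[float, np.ndarray] = {}
    for s in sigmas:
        g = px if s == 0 else ndimage.gaussian_filter(px, s)
        smoothed[s] = g
        feats.append(g)
        names.append(f"gaussian_s{s:g}")
    for s in sigmas:
        if s == 0:
            continue
        feats.append(ndimage.gaussian_gradient_magnitude(px, s))
        names.append(f"gradmag_s{s:g}")
    # offset-invariant Laplacian: the truncated LoG kernel does not sum to
    # exactly zero, so remove the mean first to make constants map to zero
    px0 = px - px.mean()
    for s in sigmas:
        if s == 0:
            continue
        feats.append(ndimage.gaussian_laplace(px0, s))
        names.append(f"laplacian_s{s:g}")
    for a, b in zip(sigmas, sigmas[1:]):
        feats.append(smoothed[a] - smoothed[b])
        names.append(f"dog_s{a:g}_s{b:g}")
    data = np.stack(feats, axis=2).astype(np.float32)
    return FeatureStack(data=data, names=tuple(names), sigma_ladder=sigmas)


@dataclass
class PixelClassifier:
    """A fitted three-class pixel classifier with its feature configuration."""

    model: RandomForestClassifier
    sigma_ladder: tuple[float, ...]
    feature_names: tuple[str, ...]
    classes: tuple[PixelClass, ...] = (
        PixelClass.CELL,
        PixelClass.BACKGROUND,
        PixelClass.INTERSPACE,
    )
    metadata: dict = field(default_factory=dict)
    feature_version: int = FEATURE_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ValueError(f"{path} does not contain a PixelClassifier")
        return obj


def train_classifier(
    images: list[RasterImage],
    annotations: list[AnnotationSet],
    n_trees: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
    sigma_ladder: tuple[float, ...] = DEFAULT_SIGMA_LADDER,
) -> PixelClassifier:
    """Train the random-forest pixel classifier from sparse annotations.

    All three classes must be represented across the annotation sets; the
    forest is seeded so identical inputs give identical classifiers. The
    in-sample accuracy on the training pixels is recorded in the metadata.
    """
    if len(images) == 0 or len(images) != len(annotations):
        raise TrainingError("need at least one image with a matching annotation set")
    present: set[PixelClass] = set()
    X_parts, y_parts = [], []
    for img, ann in zip(images, annotations):
        h, w = img.shape
        if np.any(ann.rows >= h) or np.any(ann.cols >= w):
            raise TrainingError("annotation coordinates fall outside the image")
        present |= ann.present_classes()
        fs = compute_features(img, sigma_ladder)
        X_parts.append(fs.data[ann.rows, ann.cols, :])
        y_parts.append(ann.classes)
    missing = [c.name for c in PixelClass if c not in present]
    if missing:
        raise TrainingError(f"annotations are missing class(es): {', '.join(missing)}")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    model = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    acc = float(model.score(X, y))
    n_per_class = {PixelClass(int(c)).name: int((y == c).sum()) for c in np.unique(y)}
    fs_names = compute_features(images[0], sigma_ladder).names
    return PixelClassifier(
        model=model,
        sigma_ladder=tuple(float(s) for s in sigma_ladder),
        feature_names=fs_names,
        metadata={
            "n_pixels_per_class": n_per_class,
            "seed": seed,
            "n_trees": n_trees,
            "max_depth": max_depth,
            "in_sample_accuracy": acc,
        },
    )


def predict_probabilities(classifier: PixelClassifier, image: RasterImage) -> ProbabilityMap:
    """Apply a trained classifier to an image, returning a valid probability map."""
    if image.pixels.size == 0:
        raise ValueError("cannot classify an empty image")
    fs = compute_features(image, classifier.sigma_ladder)
    if fs.names != classifier.feature_names or fs.version != classifier.feature_version:
        raise ValueError("feature configuration does not match the classifier")
    proba = classifier.model.predict_proba(fs.as_matrix())
    h, w = image.shape
    out = np.zeros((h * w, 3), dtype=np.float64)
    for j, cls in enumerate(classifier.model.classes_):
        out[:, int(cls) - 1] = proba[:, j]
    return ProbabilityMap(out.reshape(h, w, 3), image.pixel_size)


def binarize(prob: ProbabilityMap, threshold: float = 0.5, min_hole_px: int = 0) -> np.ndarray:
    """Binary cell mask: P(CELL) ≥ threshold, then fill holes smaller than min_hole_px.

    INTERSPACE and BACKGROUND probability both map to off, so seams between
    touching cells break the mask apart. Hole filling only affects holes of
    area strictly below ``min_hole_px``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mask = prob.p(PixelClass.CELL) >= threshold
    if min_hole_px > 1:
        from skimage.morphology import remove_small_holes

        # max_size fills holes of area <= value, hence strictly below min_hole_px
        mask = remove_small_holes(mask, max_size=min_hole_px - 1)
    return mask
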