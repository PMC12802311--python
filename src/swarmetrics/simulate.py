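"""Seeded synthetic dense-swarm scene generator.

Renders phase-contrast-like monolayer scenes of dark, bent rod-shaped cells
on a gray agar background, with thin brighter seams between touching cells
(the "intercellular space" signal), faint flagella-like filaments, sub-µm
debris, and an optional fluorescence channel whose per-cell intensity is
weakly linearly coupled to cell length. Every scene carries full ground
truth (backbones, true morphometrics, label raster) so the downstream
segmentation and measurement stages can be benchmarked without real data.

Geometry model: a cell is a constant-width tube swept along a curved
backbone with hemispherical pole caps, so its total length equals the
backbone arc length plus one width. Backbones are heading random-walks with
bounded curvature, rescaled so the arc/chord ratio hits a sampled sinuosity
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import RasterImage, LabelImage

# Rendered intensity levels (arbitrary units in [0, 1]); chosen so that the
# three classifier classes are separable but overlap after PSF blur + noise.
BACKGROUND_LEVEL = 0.50
CELL_LEVEL = 0.18
SEAM_LEVEL = 0.68
FILAMENT_LEVEL = 0.58
DEBRIS_LEVEL = 0.25
FLUOR_BACKGROUND_LEVEL = 0.20


class DensityError(RuntimeError):
    """Raised when rejection sampling cannot place all objects at the requested density."""


@dataclass(frozen=True)
class Distribution:
    """A small declarative distribution spec used by :class:`SceneConfig`.

    Supported kinds:

    - ``fixed``: degenerate at ``value``.
    - ``uniform``: uniform on [``low``, ``high``].
    - ``truncnorm``: normal(``mean``, ``sd``) truncated to [``low``, ``high``]
      by rejection.
    - ``one_plus_exponential``: 1 + Exponential(``scale``), truncated above at
      ``high`` (used for sinuosity, support ≥ 1).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.kind == "fixed":
            return np.full(n, float(p["value"]))
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.kind == "truncnorm":
            lo, hi = float(p["low"]), float(p["high"])
            out = np.empty(n)
            filled = 0
            # rejection sampling; the truncation windows used here keep the
            # acceptance rate high so this terminates quickly
            for _ in range(1000):
                draw = rng.normal(p["mean"], p["sd"], size=max(n - filled, 1) * 2)
                ok = draw[(draw >= lo) & (draw <= hi)]
                take = min(ok.size, n - filled)
                out[filled : filled + take] = ok[:take]
                filled += take
                if filled == n:
                    return out
            raise RuntimeError("truncnorm rejection sampling failed to converge")
        if self.kind == "one_plus_exponential":
            hi = float(p.get("high", np.inf))
            out = 1.0 + rng.exponential(p["scale"], size=n)
            return np.minimum(out, hi)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.kind == "fixed":
            return (float(p["value"]), float(p["value"]))
        if self.kind == "uniform":
            return (float(p["low"]), float(p["high"]))
        if self.kind == "truncnorm":
            return (float(p["low"]), float(p["high"]))
        if self.kind == "one_plus_exponential":
            return (1.0, float(p.get("high", np.inf)))
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "Distribution":
        d = dict(d)
        kind = d.pop("kind")
        return cls(kind, d)


@dataclass(frozen=True)
class FluorescenceModel:
    """Linear per-cell intensity model: intensity = slope·length + intercept + ε.

    The noise standard deviation is calibrated from ``r_squared_target`` via
    the simple-regression identity R² = Var(fit)/Var(total), which gives
    σ² = slope²·Var(length)·(1 − R²)/R².
    """

    slope: float = 0.0276  # a.u. per µm
    intercept: float = 0.84336  # a.u.
    r_squared_target: float = 0.3177

    def noise_sd(self, length_variance: float) -> float:
        r = self.r_squared_target
        if not (0 < r < 1):
            raise ValueError(f"r_squared_target must be in (0, 1), got {r}")
        return abs(self.slope) * math.sqrt(length_variance * (1.0 - r) / r)


def _default_short_dist() -> Distribution:
    return Distribution("truncnorm", {"mean": 2.8, "sd": 0.7, "low": 1.2, "high": 4.0})


def _default_long_dist() -> Distribution:
    return Distribution("truncnorm", {"mean": 6.5, "sd": 2.0, "low": 4.05, "high": 16.0})


def _default_width_dist() -> Distribution:
    # the source strains show minimal width change over the swarm cycle;
    # this narrow band is a documented placeholder, not a measured value
    return Distribution("truncnorm", {"mean": 0.8, "sd": 0.05, "low": 0.6, "high": 1.0})


def _default_sinuosity_dist() -> Distribution:
    return Distribution("one_plus_exponential", {"scale": 0.03, "high": 1.30})


def _default_debris_dist() -> Distribution:
    return Distribution("uniform", {"low": 0.3, "high": 1.0})


@dataclass
class SceneConfig:
    """Parameters of one synthetic dense-swarm scene.

    Lengths are physical (µm); the 4 µm short/long boundary and the 1 µm
    debris bound are hard category limits enforced on the distributions.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.1  # µm/px
    n_cells: int = 200
    long_fraction: float = 0.2
    short_length_dist: Distribution = field(default_factory=_default_short_dist)
    long_length_dist: Distribution = field(default_factory=_default_long_dist)
    width_dist: Distribution = field(default_factory=_default_width_dist)
    sinuosity_dist: Distribution = field(default_factory=_default_sinuosity_dist)
    n_debris: int = 30
    debris_length_dist: Distribution = field(default_factory=_default_debris_dist)
    filament_density: float = 0.3  # filaments per 100 µm²
    fluorescence_model: Optional[FluorescenceModel] = None
    noise_sd: float = 0.02  # additive Gaussian intensity noise, a.u.
    psf_sigma: float = 1.0  # Gaussian PSF sigma, px
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_cells < 0 or self.n_debris < 0:
            raise ValueError("object counts must be non-negative")
        if not (0.0 <= self.long_fraction <= 1.0):
            raise ValueError("long_fraction must be in [0, 1]")
        lo, hi = self.short_length_dist.support()
        if lo <= 1.0 or hi > 4.0:
            raise ValueError("short lengths must lie in (1, 4] µm")
        lo, hi = self.long_length_dist.support()
        if lo <= 4.0:
            raise ValueError("long lengths must exceed 4 µm")
        lo, hi = self.debris_length_dist.support()
        if hi > 1.0:
            raise ValueError("debris lengths must be ≤ 1 µm")
        lo, _ = self.sinuosity_dist.support()
        if lo < 1.0:
            raise ValueError("sinuosity must be ≥ 1")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be non-negative")


@dataclass
class CellTruth:
    id: int
    backbone: np.ndarray  # (m, 2) polyline, (row, col) in µm
    true_length: float  # µm, backbone arc length + width (pole caps)
    true_width: float  # µm
    true_sinuosity: float  # arc/chord, ≥ 1
    true_mean_intensity: Optional[float] = None  # a.u., background-subtracted


@dataclass
class DebrisTruth:
    id: int
    true_length: float  # µm


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``seam_mask`` and ``filament_mask`` are rendering byproducts kept so that
    training annotations for the intercellular-space class can be bootstrapped
    from truth instead of hand tracing.
    """

    cells: list[CellTruth]
    debris: list[DebrisTruth]
    label_image: LabelImage
    seam_mask: np.ndarray = None
    filament_mask: np.ndarray = None

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.cells:
            rows.append(
                {
                    "id": c.id,
                    "kind": "cell",
                    "length_um": c.true_length,
                    "width_um": c.true_width,
                    "sinuosity": c.true_sinuosity,
                    "mean_intensity_au": (
                        np.nan if c.true_mean_intensity is None else c.true_mean_intensity
                    ),
                }
            )
        for d in self.debris:
            rows.append(
                {
                    "id": d.id,
                    "kind": "debris",
                    "length_um": d.true_length,
                    "width_um": np.nan,
                    "sinuosity": np.nan,
                    "mean_intensity_au": np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["id", "kind", "length_um", "width_um", "sinuosity", "mean_intensity_au"],
        )


# ---------------------------------------------------------------------------
# backbone construction


def _make_backbone(
    rng: np.random.Generator, arc_len_um: float, sinuosity: float, step_um: float
) -> tuple[np.ndarray, float]:
    """Curved polyline of given arc length whose arc/chord ratio hits `sinuosity`.

    A smooth random heading profile is scaled by bisection until the achieved
    sinuosity is within 2% of the target. Returns (points (m,2) in µm centered
    at the polyline centroid, achieved sinuosity).
    """
    n = max(int(round(arc_len_um / step_um)), 4)
    step = arc_len_um / n

    def build(amp: float, profile: np.ndarray) -> np.ndarray:
        theta = amp * profile
        d = np.empty((n, 2))
        d[:, 0] = np.sin(theta) * step
        d[:, 1] = np.cos(theta) * step
        pts = np.vstack([[0.0, 0.0], np.cumsum(d, axis=0)])
        return pts

    def sinu_of(pts: np.ndarray) -> float:
        chord = float(np.hypot(*(pts[-1] - pts[0])))
        return arc_len_um / max(chord, 1e-9)

    for _ in range(8):
        raw = rng.standard_normal(n)
        raw = ndimage.gaussian_filter1d(raw, sigma=max(n / 8.0, 1.0), mode="nearest")
        prof = np.cumsum(raw)
        prof -= prof.mean()
        scale = np.abs(prof).max()
        if scale < 1e-9:
            continue
        prof /= scale  # heading deviations bounded by the amplitude
        if sinuosity <= 1.0 + 1e-9:
            pts = build(0.0, prof)
            return pts - pts.mean(axis=0), 1.0
        # expand until target bracketed
        hi = 0.5
        for _ in range(24):
            if sinu_of(build(hi, prof)) >= sinuosity:
                break
            hi *= 1.5
        else:
            continue  # this heading profile cannot bend enough; redraw
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            s = sinu_of(build(mid, prof))
            if s < sinuosity:
                lo = mid
            else:
                hi = mid
        pts = build(hi, prof)
        achieved = sinu_of(pts)
        if abs(achieved - sinuosity) / sinuosity <= 0.02:
            return pts - pts.mean(axis=0), achieved
    # fall back to the best achievable straightness
    pts = build(0.0, prof)
    return pts - pts.mean(axis=0), 1.0


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return pts[:1]
    m = max(int(math.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, m)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def _rasterize_tube(
    pts_px: np.ndarray, half_width_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pixels within half_width of the polyline (round caps), clipped to `shape`.

    Returns (rows, cols, unclipped_count) where unclipped_count is the pixel
    count the object would have on an infinite canvas.
    """
    dense = _resample_polyline(pts_px, 0.5)
    r0 = math.floor(dense[:, 0].min() - half_width_px - 1)
    r1 = math.ceil(dense[:, 0].max() + half_width_px + 2)
    c0 = math.floor(dense[:, 1].min() - half_width_px - 1)
    c1 = math.ceil(dense[:, 1].max() + half_width_px + 2)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(dense)
    dist, _ = tree.query(grid, k=1)
    inside = dist <= half_width_px
    rows = rr.ravel()[inside]
    cols = cc.ravel()[inside]
    unclipped = int(rows.size)
    keep = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[keep], cols[keep], unclipped


# ---------------------------------------------------------------------------
# scene assembly


def _place_objects(
    rng: np.random.Generator,
    labels: np.ndarray,
    specs: list[dict],
    pixel_size: float,
    max_attempts: int = 300,
    min_visible_fraction: float = 0.6,
) -> list[dict]:
    """Place tube objects by rejection sampling without pixel overlap.

    Each spec carries a centered backbone (µm) and half-width; placement
    samples a center and rotation, rasterizes, and commits if no pixel is
    already occupied and at least `min_visible_fraction` of the body is in
    frame. Objects are placed in the given order (callers sort large-first).
    """
    h, w = labels.shape
    placed = []
    for spec in specs:
        bb = spec["backbone"]
        hw_px = spec["half_width_um"] / pixel_size
        ok = False
        for _ in range(max_attempts):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            crow = rng.uniform(0.0, h * pixel_size)
            ccol = rng.uniform(0.0, w * pixel_size)
            rot = np.array(
                [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
            )
            pts_um = bb @ rot.T + np.array([crow, ccol])
            pts_px = pts_um / pixel_size
            rows, cols, unclipped = _rasterize_tube(pts_px, hw_px, labels.shape)
            if rows.size == 0 or rows.size < min_visible_fraction * unclipped:
                continue
            if np.any(labels[rows, cols] != 0):
                continue
            labels[rows, cols] = spec["id"]
            placed.append({**spec, "backbone_um": pts_um})
            ok = True
            break
        if not ok:
            raise DensityError(
                f"could not place object id={spec['id']} after {max_attempts} attempts; "
                "scene density is infeasible — reduce n_cells/n_debris or enlarge the image"
            )
    return placed


def _seam_pixels(cell_labels: np.ndarray) -> np.ndarray:
    """1-px seam: pixels of a cell whose 8-neighborhood contains a higher cell label."""
    mx = ndimage.maximum_filter(cell_labels, size=3)
    return (cell_labels > 0) & (mx > cell_labels)


def generate_scene(
    config: SceneConfig,
) -> tuple[RasterImage, Optional[RasterImage], SceneTruth]:
    """Generate one seeded synthetic dense-swarm scene.

    Returns the phase-contrast-like image, the fluorescence channel (``None``
    unless ``config.fluorescence_model`` is set), and the ground truth.
    Identical configs (including seed) give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    ps = config.pixel_size
    labels = np.zeros((h, w), dtype=np.uint16)

    # --- sample cell parameters
    n = config.n_cells
    is_long = rng.random(n) < config.long_fraction
    lengths = np.empty(n)
    n_long = int(is_long.sum())
    if n_long:
        lengths[is_long] = config.long_length_dist.sample(rng, n_long)
    if n - n_long:
        lengths[~is_long] = config.short_length_dist.sample(rng, n - n_long)
    widths = config.width_dist.sample(rng, n)
    widths = np.minimum(widths, lengths * 0.8)  # keep rods longer than wide
    sinuosities = config.sinuosity_dist.sample(rng, n)

    cell_specs = []
    for i in range(n):
        arc = max(lengths[i] - widths[i], 0.2 * lengths[i])
        bb, achieved = _make_backbone(rng, arc, float(sinuosities[i]), ps)
        cell_specs.append(
            {
                "id": i + 1,
                "backbone": bb,
                "half_width_um": widths[i] / 2.0,
                "true_length": arc + widths[i],
                "true_width": float(widths[i]),
                "true_sinuosity": achieved,
            }
        )
    # place longest first: large bodies need open space
    order = np.argsort([-s["true_length"] for s in cell_specs])
    placed_cells = _place_objects(rng, labels, [cell_specs[i] for i in order], ps)
    placed_cells.sort(key=lambda s: s["id"])

    # --- debris: sub-µm specks
    debris_specs = []
    if config.n_debris:
        dlen = config.debris_length_dist.sample(rng, config.n_debris)
        dwid = rng.uniform(0.2, 0.4, size=config.n_debris)
        dwid = np.minimum(dwid, dlen * 0.8)
        for j in range(config.n_debris):
            arc = max(dlen[j] - dwid[j], 0.05)
            bb, _ = _make_backbone(rng, arc, 1.0, ps)
            debris_specs.append(
                {
                    "id": n + 1 + j,
                    "backbone": bb,
                    "half_width_um": dwid[j] / 2.0,
                    "true_length": arc + dwid[j],
                }
            )
    placed_debris = _place_objects(rng, labels, debris_specs, ps)

    cell_labels = np.where(labels <= n, labels, 0).astype(np.int64)
    debris_mask = labels > n
    seam = _seam_pixels(cell_labels)

    # --- filaments: faint thin curves on background only (not labeled)
    area_um2 = h * w * ps * ps
    n_fil = int(round(config.filament_density * area_um2 / 100.0))
    filament = np.zeros((h, w), dtype=bool)
    for _ in range(n_fil):
        flen = rng.uniform(3.0, 10.0)
        bb, _ = _make_backbone(rng, flen, float(rng.uniform(1.02, 1.3)), ps)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        pts = (bb @ rot.T + np.array([rng.uniform(0, h * ps), rng.uniform(0, w * ps)])) / ps
        rows, cols, _ = _rasterize_tube(pts, 0.75, (h, w))
        filament[rows, cols] = True
    filament &= labels == 0

    # --- phase rendering
    phase = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    phase[filament] = FILAMENT_LEVEL
    phase[debris_mask] = DEBRIS_LEVEL
    phase[cell_labels > 0] = CELL_LEVEL
    phase[seam] = SEAM_LEVEL
    if config.psf_sigma > 0:
        phase = ndimage.gaussian_filter(phase, config.psf_sigma)
    if config.noise_sd > 0:
        phase = phase + rng.normal(0.0, config.noise_sd, size=(h, w))

    # --- fluorescence channel
    fluor_img = None
    intensities = None
    if config.fluorescence_model is not None and n > 0:
        model = config.fluorescence_model
        placed_lengths = np.array([s["true_length"] for s in placed_cells])
        sd = model.noise_sd(float(np.var(placed_lengths)))
        intensities = (
            model.slope * placed_lengths + model.intercept + rng.normal(0.0, sd, size=n)
        )
        fl = np.full((h, w), FLUOR_BACKGROUND_LEVEL, dtype=np.float64)
        for s, v in zip(placed_cells, intensities):
            fl[cell_labels == s["id"]] = FLUOR_BACKGROUND_LEVEL + v
        if config.noise_sd > 0:
            fl = fl + rng.normal(0.0, config.noise_sd, size=(h, w))
        fluor_img = RasterImage(fl, ps)

    truth = SceneTruth(
        cells=[
            CellTruth(
                id=s["id"],
                backbone=s["backbone_um"],
                true_length=float(s["true_length"]),
                true_width=float(s["true_width"]),
                true_sinuosity=float(s["true_sinuosity"]),
                true_mean_intensity=(
                    float(intensities[k]) if intensities is not None else None
                ),
            )
            for k, s in enumerate(placed_cells)
        ],
        debris=[
            DebrisTruth(id=s["id"], true_length=float(s["true_length"]))
            for s in placed_debris
        ],
        label_image=LabelImage(labels.astype(np.int32), ps),
        seam_mask=seam,
        filament_mask=filament,
    )
    return RasterImage(phase, ps), fluor_img, truth


# ---------------------------------------------------------------------------
# study-condition presets and model-level sampling


_LONG_FRACTION_BY_HOUR = {2: 0.10, 3: 0.18, 4: 0.32, 5: 0.45, 6: 0.60, 7: 0.42, 8: 0.30}
_LONG_MEAN_BY_HOUR = {2: 5.5, 3: 6.0, 4: 7.0, 5: 8.0, 6: 9.0, 7: 7.0, 8: 6.0}


def timecourse_presets(hour: int) -> SceneConfig:
    """Scene config emulating one hour of the swarm development cycle.

    The long-cell fraction rises to a maximum (> 0.5) at hour 6 — when
    collective migration peaks and elongated swarmer cells dominate — and
    falls again through hours 7–8 (consolidation); the long-length scale
    follows the same rise and fall. Hours outside 2–8 are rejected.
    """
    if not (isinstance(hour, (int, np.integer)) and 2 <= hour <= 8):
        raise ValueError(f"hour must be an integer in 2..8, got {hour!r}")
    cfg = SceneConfig(
        image_size=(1200, 1200),
        pixel_size=0.1,
        n_cells=650,
        long_fraction=_LONG_FRACTION_BY_HOUR[hour],
        long_length_dist=Distribution(
            "truncnorm",
            {"mean": _LONG_MEAN_BY_HOUR[hour], "sd": 2.0, "low": 4.05, "high": 16.0},
        ),
        n_debris=40,
        filament_density=0.3,
        seed=hour,
    )
    cfg.validate()
    return cfg


def sample_fluorescence_population(
    n: int,
    model: FluorescenceModel = None,
    long_fraction: float = 0.35,
    short_length_dist: Distribution = None,
    long_length_dist: Distribution = None,
    seed: int = 0,
):
    """Sample (length, intensity) pairs from the per-cell fluorescence model.

    This is the generative model behind the fluorescence channel of
    :func:`generate_scene`, exposed at the population level so regression
    recovery can be studied at large n without rendering images. Returns a
    DataFrame with columns ``length_um`` and ``mean_intensity_au``.
    """
    import pandas as pd

    if model is None:
        model = FluorescenceModel()
    if short_length_dist is None:
        short_length_dist = _default_short_dist()
    if long_length_dist is None:
        long_length_dist = _default_long_dist()
    rng = np.random.default_rng(seed)
    is_long = rng.random(n) < long_fraction
    lengths = np.empty(n)
    n_long = int(is_long.sum())
    if n_long:
        lengths[is_long] = long_length_dist.sample(rng, n_long)
    if n - n_long:
        lengths[~is_long] = short_length_dist.sample(rng, n - n_long)
    sd = model.noise_sd(float(np.var(lengths)))
    intensity = model.slope * lengths + model.intercept + rng.normal(0.0, sd, size=n)
    return pd.DataFrame({"length_um": lengths, "mean_intensity_au": intensity})


def annotations_from_truth(
    truth: SceneTruth, n_per_class: int = 3000, seed: int = 0
):
    """Bootstrap sparse training annotations from scene ground truth.

    Emulates manual tracing: CELL strokes come from cell interiors (truth
    labels eroded by 1 px), BACKGROUND from pixels at least 2 px away from
    any object, INTERSPACE from inter-cell seams plus filament pixels.
    Returns an :class:`~swarmetrics.segment.AnnotationSet`.
    """
    from .segment import AnnotationSet, PixelClass

    rng = np.random.default_rng(seed)
    labels = truth.label_image.labels
    n_cell_ids = len(truth.cells)
    cell_mask = (labels > 0) & (labels <= n_cell_ids)
    inter = np.zeros_like(cell_mask)
    if truth.seam_mask is not None:
        inter |= truth.seam_mask
    if truth.filament_mask is not None:
        inter |= truth.filament_mask
    interior = ndimage.binary_erosion(cell_mask, iterations=1) & ~inter
    if not interior.any():
        interior = cell_mask & ~inter
    bg = ~ndimage.binary_dilation(labels > 0, iterations=2) & ~inter

    rows, cols, classes = [], [], []
    for mask, cls in (
        (interior, PixelClass.CELL),
        (bg, PixelClass.BACKGROUND),
        (inter, PixelClass.INTERSPACE),
    ):
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            continue
        k = min(n_per_class, rr.size)
        pick = rng.choice(rr.size, size=k, replace=False)
        rows.append(rr[pick])
        cols.append(cc[pick])
        classes.append(np.full(k, int(cls)))
    return AnnotationSet(
        image_ref="synthetic-truth",
        rows=np.concatenate(rows),
        cols=np.concatenate(cols),
        classes=np.concatenate(classes),
    )
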