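"""Medial-axis morphometry of labeled particles and the debris-filter cascade.

Curved rod-shaped cells are measured along their skeleton: length is the
geodesic length of the longest skeleton path plus one width (accounting for
the two hemispherical pole caps), width is twice the mean medial-axis
distance-transform value, and sinuosity is the geodesic/chord ratio of the
skeleton path. Debris is removed by the filter cascade: area ≥ 1 µm²,
circularity in [0, 0.9], length strictly > 1 µm, and edge-touching
particles excluded. Cells are typed SHORT (≤ 4 µm) or LONG (> 4 µm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import skeletonize

from .types import LabelImage

SHORT = "SHORT"
LONG = "LONG"
LENGTH_SPLIT_UM = 4.0  # short/long boundary: ≤ 4 µm is SHORT, > 4 µm is LONG

RECORD_COLUMNS = [
    "id",
    "length_um",
    "width_um",
    "area_um2",
    "perimeter_um",
    "sinuosity",
    "circularity",
    "centroid_row_um",
    "centroid_col_um",
    "touches_edge",
    "mean_intensity_au",
    "type",
]


@dataclass(frozen=True)
class CellRecord:
    """Morphometrics of one particle. Physical units throughout (µm, µm², a.u.)."""

    id: int
    length_um: float
    width_um: float
    area_um2: float
    perimeter_um: float
    sinuosity: float
    circularity: float
    centroid_row_um: float
    centroid_col_um: float
    touches_edge: bool
    mean_intensity_au: float = float("nan")
    type: str = SHORT


@dataclass(frozen=True)
class FilterConfig:
    """The debris-filter cascade bounds.

    Area and circularity bounds are inclusive; the length bound is strictly
    exclusive (objects of exactly 1 µm count as debris). Defaults follow the
    cascade used for dense swarm monolayers: area 1 µm² to max, circularity
    0–0.9, length > 1 µm, edge-touching particles excluded.
    """

    min_area_um2: float = 1.0
    circularity_range: tuple[float, float] = (0.0, 0.9)
    min_length_um: float = 1.0
    exclude_edges: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.circularity_range
        if self.min_area_um2 < 0 or self.min_length_um < 0 or lo < 0:
            raise ValueError("filter bounds must be non-negative")
        if lo > hi:
            raise ValueError("circularity_range must be ordered")


def label_particles(
    mask: np.ndarray, pixel_size: float, connectivity: int = 8
) -> LabelImage:
    """Connected-component labeling of a binary mask.

    Labels are assigned in deterministic row-major order of each component's
    first pixel. Connectivity 8 (the default) keeps thin diagonal cell
    bodies connected; 4 splits diagonal contacts.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    structure = (
        ndimage.generate_binary_structure(2, 2)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    raw, n = ndimage.label(mask, structure=structure)
    if n:
        # enforce row-major first-pixel ordering of the label values
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        idx = np.flatnonzero(flat)
        np.minimum.at(first, flat[idx], idx)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    return LabelImage(raw.astype(np.int32), pixel_size)


def _skeleton_longest_path(skel: np.ndarray) -> tuple[float, np.ndarray]:
    """Geodesic length (px) and pixel path of the longest skeleton path.

    The skeleton pixel graph (8-connectivity, step weights 1/√2) is swept
    twice with Dijkstra: farthest node from an arbitrary start, then
    farthest from that — exact on trees, which skeletons of filled particles
    are. Selecting the single longest path implicitly prunes short side
    branches so skeletonization spurs do not inflate length or sinuosity.
    """
    rr, cc = np.nonzero(skel)
    npix = rr.size
    if npix == 0:
        return 0.0, np.empty((0, 2), dtype=np.int64)
    if npix == 1:
        return 0.0, np.column_stack([rr, cc])
    index = -np.ones(skel.shape, dtype=np.int64)
    index[rr, cc] = np.arange(npix)
    rows_l, cols_l, w_l = [], [], []
    for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))):
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < skel.shape[0]) & (c2 >= 0) & (c2 < skel.shape[1])
        ok[ok] &= skel[r2[ok], c2[ok]]
        a = index[rr[ok], cc[ok]]
        b = index[r2[ok], c2[ok]]
        rows_l.append(a)
        cols_l.append(b)
        w_l.append(np.full(a.size, w))
    a = np.concatenate(rows_l)
    b = np.concatenate(cols_l)
    w = np.concatenate(w_l)
    graph = coo_matrix((w, (a, b)), shape=(npix, npix)).tocsr()

    d0 = dijkstra(graph, directed=False, indices=0)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du, pred = dijkstra(graph, directed=False, indices=u, return_predecessors=True)
    du[~np.isfinite(du)] = -1
    v = int(np.argmax(du))
    length = float(du[v])
    path = [v]
    while path[-1] != u and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    path = np.asarray(path[::-1])
    return length, np.column_stack([rr[path], cc[path]])


def _measure_crop(crop_mask: np.ndarray, pixel_size: float) -> dict:
    """Length/width/sinuosity/perimeter of a single-particle binary crop."""
    ps = pixel_size
    padded = np.pad(crop_mask, 2)
    edt = ndimage.distance_transform_edt(padded)
    skel = skeletonize(padded)
    _, path = _skeleton_longest_path(skel)
    if path.shape[0] >= 2:
        # trim path ends where the medial-axis radius drops below the body's
        # half-width: removes skeletonization hooks at square ends and puts
        # the endpoints where the pole caps begin, matching the +width cap
        # correction below
        radii = edt[path[:, 0], path[:, 1]]
        # robust half-width reference: spur tails diving toward the boundary
        # carry small radii and would drag a plain mean down
        half_w = float(np.percentile(radii, 75))
        good = np.flatnonzero(radii >= 0.9 * half_w)
        if good.size >= 2:
            # never trim more than the pole-cap scale from either end
            cap = int(math.ceil(half_w))
            path = path[min(good[0], cap) : max(good[-1] + 1, path.shape[0] - cap)]
        width_px = 2.0 * float(edt[path[:, 0], path[:, 1]].mean())
        # smooth the pixel chain before measuring: raw skeleton paths zigzag
        # at the pixel scale, which inflates arc length and sinuosity
        pf = path.astype(float)
        win = min(3, pf.shape[0])
        if win >= 3:
            pf = ndimage.uniform_filter1d(pf, size=win, axis=0, mode="nearest")
        steps = np.hypot(*np.diff(pf, axis=0).T)
        geo_px = float(steps.sum())
        chord_px = float(np.hypot(*(pf[-1] - pf[0])))
        sinuosity = max(geo_px / chord_px, 1.0) if chord_px > 1e-9 else 1.0
    else:
        # particle below skeleton resolution: treat as a blob
        geo_px = 0.0
        width_px = 2.0 * float(edt.max())
        sinuosity = 1.0
    width = width_px * ps
    length = max(geo_px * ps + width, width)
    perim = float(perimeter_crofton(padded, directions=4)) * ps
    return {
        "length_um": length,
        "width_um": width,
        "sinuosity": sinuosity,
        "perimeter_um": max(perim, 2.0 * ps),
    }


def measure_particle(labels: LabelImage, id: int) -> CellRecord:
    """Measure one labeled particle. Raises ``KeyError`` for an unknown id."""
    mask = labels.labels == id
    if not mask.any():
        raise KeyError(f"label {id} not present in the label image")
    return _measure_from_mask(mask, int(id), labels)


def _measure_from_mask(mask: np.ndarray, pid: int, labels: LabelImage) -> CellRecord:
    ps = labels.pixel_size
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    crop = mask[r0 : r1 + 1, c0 : c1 + 1]
    m = _measure_crop(crop, ps)
    area = float(rr.size) * ps * ps
    circ = min(1.0, 4.0 * math.pi * area / m["perimeter_um"] ** 2)
    h, w = labels.shape
    touches = bool(r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1)
    rec = CellRecord(
        id=pid,
        length_um=m["length_um"],
        width_um=m["width_um"],
        area_um2=area,
        perimeter_um=m["perimeter_um"],
        sinuosity=m["sinuosity"],
        circularity=circ,
        centroid_row_um=float(rr.mean()) * ps,
        centroid_col_um=float(cc.mean()) * ps,
        touches_edge=touches,
        type=SHORT if m["length_um"] <= LENGTH_SPLIT_UM else LONG,
    )
    return rec


def measure_all(labels: LabelImage) -> pd.DataFrame:
    """Measure every labeled particle; one row per label, ordered by label id."""
    records = []
    lab = labels.labels
    for region in regionprops(lab):
        sl = region.slice
        mask = np.zeros(lab.shape, dtype=bool)
        mask[sl] = lab[sl] == region.label
        records.append(_measure_from_mask(mask, int(region.label), labels))
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    df = pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
    return df.sort_values("id", ignore_index=True)


def apply_filters(records: pd.DataFrame, config: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Apply the debris-filter cascade; returns surviving rows, order preserved.

    Keeps records with area ≥ min_area, circularity inside the (inclusive)
    range, length strictly above min_length, and — when edge exclusion is on
    — not touching the raster border. The input table is never mutated.
    """
    if records.empty:
        return records.copy()
    lo, hi = config.circularity_range
    keep = (
        (records["area_um2"] >= config.min_area_um2)
        & (records["circularity"] >= lo)
        & (records["circularity"] <= hi)
        & (records["length_um"] > config.min_length_um)
    )
    if config.exclude_edges:
        keep &= ~records["touches_edge"].astype(bool)
    return records.loc[keep].copy()


def classify_length(records: pd.DataFrame, split: float = LENGTH_SPLIT_UM) -> pd.DataFrame:
    """Assign SHORT/LONG subpopulation type: length ≤ split is SHORT, > split is LONG."""
    if not records.empty and (records["length_um"] <= 0).any():
        raise ValueError("lengths must be positive")
    out = records.copy()
    out["type"] = np.where(out["length_um"] > split, LONG, SHORT)
    return out
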