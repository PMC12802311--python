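"""Detection benchmarking against synthetic-scene ground truth.

Matches predicted particles to ground-truth cells by intersection-over-union
and reports the recovered fraction, the audit the pipeline uses to mirror a
by-hand counting benchmark.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import LabelImage

DEFAULT_EVAL_HOURS = (2, 3, 4, 5, 6)
DEFAULT_TRAIN_HOURS = (2, 6)


def match_components(
    truth_labels: LabelImage,
    pred_labels: LabelImage,
    truth_ids: np.ndarray,
    pred_ids: np.ndarray | None = None,
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Best-IoU match of each ground-truth particle to a predicted particle.

    Returns one row per truth id with its best-matching predicted id, the
    IoU, and whether it counts as detected (best IoU ≥ threshold against a
    predicted particle in ``pred_ids``, all predicted particles if None).
    """
    t = truth_labels.labels
    p = pred_labels.labels
    if t.shape != p.shape:
        raise ValueError("label rasters are not aligned")
    truth_ids = np.asarray(truth_ids)
    t_areas = np.bincount(t.ravel())
    p_areas = np.bincount(p.ravel())
    both = (t > 0) & (p > 0)
    # pair intersection counts via a joint key
    key = t[both].astype(np.int64) * (p.max() + 1) + p[both].astype(np.int64)
    uniq, counts = np.unique(key, return_counts=True)
    tt = uniq // (p.max() + 1)
    pp = uniq % (p.max() + 1)
    allowed = None if pred_ids is None else set(int(i) for i in np.asarray(pred_ids))
    best: dict[int, tuple[float, int]] = {}
    for ti, pi, inter in zip(tt, pp, counts):
        if allowed is not None and int(pi) not in allowed:
            continue
        union = t_areas[ti] + p_areas[pi] - inter
        iou = inter / union if union else 0.0
        cur = best.get(int(ti), (0.0, 0))
        if iou > cur[0]:
            best[int(ti)] = (float(iou), int(pi))
    rows = []
    for ti in truth_ids:
        iou, pi = best.get(int(ti), (0.0, 0))
        rows.append(
            {
                "truth_id": int(ti),
                "matched_pred_id": pi,
                "iou": iou,
                "detected": iou >= iou_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["truth_id", "matched_pred_id", "iou", "detected"])


def detection_rate(
    truth,
    pred_labels: LabelImage,
    surviving_ids: np.ndarray,
    iou_threshold: float = 0.5,
    exclude_edge_truth: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Fraction of ground-truth cells recovered by the pipeline.

    Ground-truth cells whose rendered pixels touch the raster border are
    excluded from the denominator when ``exclude_edge_truth`` is set,
    because the filter cascade deliberately removes edge-clipped particles;
    a benchmark over them would measure the protocol, not the detector.
    """
    t = truth.label_image.labels
    h, w = t.shape
    edge_ids = set(np.unique(np.concatenate([t[0], t[-1], t[:, 0], t[:, -1]])).tolist())
    ids = []
    for c in truth.cells:
        if exclude_edge_truth and c.id in edge_ids:
            continue
        ids.append(c.id)
    matches = match_components(
        truth.label_image, pred_labels, np.asarray(ids), surviving_ids, iou_threshold
    )
    rate = float(matches["detected"].mean()) if len(matches) else float("nan")
    return rate, matches


def run_detection_benchmark(
    seed: int = 0,
    eval_hours: tuple[int, ...] = DEFAULT_EVAL_HOURS,
    train_hours: tuple[int, ...] = DEFAULT_TRAIN_HOURS,
    n_per_class: int = 3000,
    threshold: float = 0.5,
    min_hole_px: int = 30,
    iou_threshold: float = 0.5,
) -> dict:
    """End-to-end detection benchmark on dense synthetic monolayer frames.

    Generates one timecourse-preset frame per evaluation hour (~650 cells
    each), trains the three-class pixel classifier on annotated frames from
    ``train_hours``, runs binarization, particle measurement and the debris
    filter cascade, and matches survivors to ground truth at the given IoU.
    Returns per-frame recovered fractions and their mean.
    """
    from .morphometry import FilterConfig, apply_filters, classify_length, label_particles, measure_all
    from .segment import binarize, predict_probabilities, train_classifier
    from .simulate import annotations_from_truth, generate_scene, timecourse_presets

    base = int(seed) % 1_000_000
    train_scenes = []
    annotations = []
    for i, hour in enumerate(train_hours):
        cfg = timecourse_presets(hour)
        cfg.seed = (base * 37 + 101 + i) % 2**31
        phase, _, truth = generate_scene(cfg)
        train_scenes.append(phase)
        annotations.append(
            annotations_from_truth(truth, n_per_class=n_per_class, seed=(base * 13 + 7 + i) % 2**31)
        )
    classifier = train_classifier(train_scenes, annotations, seed=base % 2**31)

    rates = []
    n_truth_total = 0
    for i, hour in enumerate(eval_hours):
        cfg = timecourse_presets(hour)
        cfg.seed = (base * 91 + 51 + i) % 2**31
        phase, _, truth = generate_scene(cfg)
        prob = predict_probabilities(classifier, phase)
        mask = binarize(prob, threshold=threshold, min_hole_px=min_hole_px)
        labels = label_particles(mask, cfg.pixel_size)
        records = measure_all(labels)
        survivors = classify_length(apply_filters(records, FilterConfig()))
        rate, matches = detection_rate(
            truth, labels, survivors["id"].to_numpy(), iou_threshold=iou_threshold
        )
        rates.append(rate)
        n_truth_total += len(matches)
    return {
        "per_frame_rates": rates,
        "mean_rate": float(np.mean(rates)),
        "n_truth_cells": int(n_truth_total),
        "classifier_accuracy": classifier.metadata["in_sample_accuracy"],
    }


def run_regression_recovery(
    seed: int = 0, n: int = 7000, n_seeds: int = 20
) -> dict:
    """Recover the fluorescence model's slope/intercept/adjusted R² by OLS.

    Draws ``n_seeds`` independent populations of ``n`` cells from the
    per-cell fluorescence model at its default coefficients and fits the
    intensity-on-length regression to each. Returns the per-seed estimates,
    their means and Monte-Carlo standard errors, and the generative targets.
    """
    from .popstats import regress_intensity_on_length
    from .simulate import FluorescenceModel, sample_fluorescence_population

    model = FluorescenceModel()
    slopes, intercepts, r2s = [], [], []
    base = int(seed) % 2**20
    for k in range(n_seeds):
        pop = sample_fluorescence_population(n, model=model, seed=(base * 101 + k) % 2**31)
        reg = regress_intensity_on_length(pop)
        slopes.append(reg.slope)
        intercepts.append(reg.intercept)
        r2s.append(reg.r_squared_adjusted)
    def _mc(v):
        v = np.asarray(v)
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "values": [float(x) for x in v],
        }
    return {
        "n": n,
        "n_seeds": n_seeds,
        "slope": _mc(slopes),
        "intercept": _mc(intercepts),
        "r_squared_adjusted": _mc(r2s),
        "targets": {
            "slope": model.slope,
            "intercept": model.intercept,
            "r_squared_adjusted": model.r_squared_target,
        },
    }
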