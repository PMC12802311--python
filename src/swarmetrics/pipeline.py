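"""End-to-end batch workflow: simulate → train → segment → measure → fluor → analyze.

A single declarative config (YAML mapping or dict) drives the run; every
stage has its own seed, every artifact is written under the output
directory, and a JSON manifest records versions, seeds, per-stage counts,
timings and every file produced. Re-running an identical config reproduces
identical tables. A stage failure halts the run with the stage named;
artifacts already written are retained.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fluor import estimate_background, measure_intensity
from .io import (
    ensure_dir,
    load_config,
    read_image,
    read_label_image,
    write_cells_csv,
    write_image,
    write_label_image,
)
from .morphometry import FilterConfig, apply_filters, classify_length, label_particles, measure_all
from .overlay import render_overlay
from .popstats import (
    pairwise_wilcoxon,
    regress_intensity_on_length,
    summaries_to_frame,
    summarize_population,
    tests_to_frame,
)
from .segment import AnnotationSet, PixelClassifier, binarize, predict_probabilities, train_classifier
from .simulate import (
    Distribution,
    FluorescenceModel,
    SceneConfig,
    annotations_from_truth,
    generate_scene,
    timecourse_presets,
)

STAGES = ("simulate", "train", "segment", "measure", "fluor", "analyze")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative run configuration.

    ``stages`` maps stage names (see :data:`STAGES`) to their parameter
    mappings; absent stages are skipped. ``pixel_size`` (µm/px) and ``seed``
    are global defaults a stage may override.
    """

    out_dir: str
    pixel_size: float = 0.1
    seed: int = 0
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        stages = {k: d.pop(k) for k in list(d) if k in STAGES}
        return cls(
            out_dir=d["out_dir"],
            pixel_size=float(d.get("pixel_size", 0.1)),
            seed=int(d.get("seed", 0)),
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_config(path))


def _scene_config_from(params: dict, pixel_size: float, seed: int) -> SceneConfig:
    params = dict(params)
    hour = params.pop("preset_hour", None)
    if hour is not None:
        cfg = timecourse_presets(int(hour))
    else:
        cfg = SceneConfig(pixel_size=pixel_size)
    for key in (
        "image_size",
        "pixel_size",
        "n_cells",
        "long_fraction",
        "n_debris",
        "filament_density",
        "noise_sd",
        "psf_sigma",
    ):
        if key in params:
            v = params.pop(key)
            setattr(cfg, key, tuple(v) if key == "image_size" else v)
    for key in (
        "short_length_dist",
        "long_length_dist",
        "width_dist",
        "sinuosity_dist",
        "debris_length_dist",
    ):
        if key in params:
            setattr(cfg, key, Distribution.from_dict(params.pop(key)))
    if "fluorescence_model" in params:
        fm = params.pop("fluorescence_model")
        cfg.fluorescence_model = None if fm is None else FluorescenceModel(**fm)
    cfg.seed = int(params.pop("seed", seed))
    if params:
        raise ValueError(f"unknown simulate parameters: {sorted(params)}")
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    from . import __version__

    out = ensure_dir(config.out_dir)
    manifest: dict = {
        "version": __version__,
        "pixel_size": config.pixel_size,
        "seed": config.seed,
        "stages": [],
        "files": [],
        "counts": {},
        "seeds": {},
        "timings_s": {},
    }

    def record(path: Path) -> str:
        rel = str(Path(path).relative_to(out))
        manifest["files"].append(rel)
        return rel

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        params = dict(config.stages[stage] or {})
        t0 = time.perf_counter()
        try:
            _run_stage(stage, params, config, out, state, manifest, record)
        except Exception as exc:  # halt with the failing stage named
            _write_manifest(out, manifest)
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _run_stage(stage, params, config, out, state, manifest, record) -> None:
    ps = config.pixel_size
    if stage == "simulate":
        cfg = _scene_config_from(params, ps, config.seed)
        manifest["seeds"]["simulate"] = cfg.seed
        phase, fluor, truth = generate_scene(cfg)
        state.update(phase=phase, fluor=fluor, truth=truth)
        write_image(out / "phase.tif", phase)
        record(out / "phase.tif")
        if fluor is not None:
            write_image(out / "fluorescence.tif", fluor)
            record(out / "fluorescence.tif")
        write_label_image(out / "truth_labels.tif", truth.label_image)
        record(out / "truth_labels.tif")
        truth.to_frame().to_csv(out / "truth.csv", index=False)
        record(out / "truth.csv")
        manifest["counts"]["simulate"] = {
            "cells": len(truth.cells),
            "debris": len(truth.debris),
        }
    elif stage == "train":
        seed = int(params.get("seed", config.seed))
        manifest["seeds"]["train"] = seed
        if "truth" in state:
            ann = annotations_from_truth(
                state["truth"], n_per_class=int(params.get("n_per_class", 3000)), seed=seed
            )
            images = [state["phase"]]
            annotations = [ann]
        else:
            images = [read_image(p, ps) for p in params["images"]]
            annotations = [
                AnnotationSet.from_label_raster(read_label_image(p, ps).labels, str(p))
                for p in params["labels"]
            ]
        clf = train_classifier(
            images,
            annotations,
            n_trees=int(params.get("n_trees", 100)),
            max_depth=params.get("max_depth"),
            seed=seed,
        )
        state["classifier"] = clf
        clf.save(out / "classifier.model")
        record(out / "classifier.model")
        manifest["counts"]["train"] = clf.metadata["n_pixels_per_class"]
    elif stage == "segment":
        clf = state.get("classifier")
        if clf is None:
            clf = PixelClassifier.load(params["model"])
        phase = state.get("phase")
        if phase is None:
            phase = read_image(params["image"], ps)
            state["phase"] = phase
        prob = predict_probabilities(clf, phase)
        mask = binarize(
            prob,
            threshold=float(params.get("threshold", 0.5)),
            min_hole_px=int(params.get("min_hole_px", 30)),
        )
        state["mask"] = mask
        from .segment import PixelClass

        write_image(out / "p_cell.tif", type(phase)(prob.p(PixelClass.CELL), ps))
        record(out / "p_cell.tif")
        write_image(out / "mask.tif", type(phase)(mask.astype(np.float32), ps))
        record(out / "mask.tif")
        manifest["counts"]["segment"] = {"on_pixels": int(mask.sum())}
    elif stage == "measure":
        mask = state.get("mask")
        if mask is None:
            mask = read_image(params["mask"], ps).pixels > 0.5
        labels = label_particles(mask, ps, connectivity=int(params.get("connectivity", 8)))
        state["labels"] = labels
        records = measure_all(labels)
        fc = FilterConfig(**params.get("filters", {}))
        survivors = classify_length(apply_filters(records, fc))
        state["records_all"] = records
        state["records"] = survivors
        write_label_image(out / "labels.tif", labels)
        record(out / "labels.tif")
        write_cells_csv(out / "cells_all.csv", records)
        record(out / "cells_all.csv")
        write_cells_csv(out / "cells.csv", survivors)
        record(out / "cells.csv")
        if "phase" in state:
            render_overlay(
                state["phase"], survivors, labels, mode="length_type", path=out / "overlay.png"
            )
            record(out / "overlay.png")
        manifest["counts"]["measure"] = {
            "particles": int(len(records)),
            "survivors": int(len(survivors)),
        }
    elif stage == "fluor":
        fluor = state.get("fluor")
        if fluor is None:
            fluor = read_image(params["fluor"], ps)
        if fluor is None:
            raise ValueError("no fluorescence channel available")
        labels = state["labels"]
        seed = int(params.get("seed", config.seed))
        manifest["seeds"]["fluor"] = seed
        bg = estimate_background(
            fluor,
            labels,
            box_size_um=float(params.get("box_size_um", 5.0)),
            n_boxes=int(params.get("n_boxes", 4)),
            seed=seed,
        )
        state["records"] = measure_intensity(fluor, labels, bg, state["records"])
        with open(out / "background.json", "w") as fh:
            fh.write(bg.to_json())
        record(out / "background.json")
        write_cells_csv(out / "cells.csv", state["records"])
        manifest["counts"]["fluor"] = {"mean_background": bg.mean_background}
    elif stage == "analyze":
        from .plots import box_whisker_plot, variance_ci_plot

        records = state.get("records")
        if records is None:
            records = pd.read_csv(params["cells"])
        group_key = params.get("group")
        seed = int(params.get("seed", config.seed))
        manifest["seeds"]["analyze"] = seed
        if group_key is None:
            records = records.copy()
            records["group"] = "all"
            group_key = "group"
        summaries = summarize_population(
            records,
            group_key,
            feature=params.get("feature", "length"),
            n_boot=int(params.get("n_boot", 1000)),
            seed=seed,
        )
        summaries_to_frame(summaries).to_csv(out / "summary.csv", index=False)
        record(out / "summary.csv")
        if records[group_key].nunique() >= 2:
            tests = pairwise_wilcoxon(records, group_key, feature=params.get("feature", "length"))
            tests_to_frame(tests).to_csv(out / "pairwise_tests.csv", index=False)
            record(out / "pairwise_tests.csv")
        if records["mean_intensity_au"].notna().sum() >= 3:
            reg = regress_intensity_on_length(records)
            with open(out / "regression.json", "w") as fh:
                json.dump(reg.__dict__, fh, indent=2)
            record(out / "regression.json")
        box_whisker_plot(records, group_key, params.get("feature", "length"), out / "boxplot.png")
        record(out / "boxplot.png")
        variance_ci_plot(summaries, out / "variance_ci.png")
        record(out / "variance_ci.png")
        manifest["counts"]["analyze"] = {"groups": int(records[group_key].nunique())}
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
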