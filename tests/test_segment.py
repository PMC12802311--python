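"""Pixel classifier: features, training, probability maps, binarization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import swarmetrics as sw
from swarmetrics.segment import PixelClass, TrainingError
from swarmetrics.types import RasterImage


def test_constant_image_features():
    img = RasterImage(np.full((40, 40), 100.0), 0.1)
    fs = sw.compute_features(img)
    for name, feat in zip(fs.names, np.moveaxis(fs.data, 2, 0)):
        if name.startswith("gaussian"):
            assert np.allclose(feat, 100.0, atol=1e-4), name
        else:
            assert np.allclose(feat, 0.0, atol=1e-4), name


def test_ramp_gradient_magnitude_is_slope():
    # intensity ramp of 2 per pixel along columns
    img = RasterImage(np.tile(2.0 * np.arange(64), (64, 1)), 0.1)
    fs = sw.compute_features(img, sigma_ladder=(1.0, 2.0))
    grad = fs.data[:, :, list(fs.names).index("gradmag_s1")]
    interior = grad[20:-20, 20:-20]
    assert np.allclose(interior, 2.0, atol=1e-3)


def test_sigma_zero_is_identity():
    px = np.random.default_rng(1).normal(size=(32, 32))
    fs = sw.compute_features(RasterImage(px, 0.1), sigma_ladder=(0.0, 2.0))
    ident = fs.data[:, :, list(fs.names).index("gaussian_s0")]
    assert np.allclose(ident, px, atol=1e-6)


def _three_level_image(rng, shape=(120, 120)):
    """Well-separated synthetic intensities: cells dark, background mid, seams bright."""
    img = np.full(shape, 0.5) + rng.normal(0, 0.01, shape)
    img[10:50, 10:50] -= 0.3  # cells
    img[70:74, 10:110] += 0.3  # seams
    labels = np.zeros(shape, dtype=np.uint8)
    labels[15:45, 15:45] = int(PixelClass.CELL)
    labels[90:110, 60:110] = int(PixelClass.BACKGROUND)
    labels[71:73, 20:100] = int(PixelClass.INTERSPACE)
    return img, labels


def _centroid_oracle_accuracy(img, ann_raster):
    """Nearest-class-centroid classification accuracy on the training pixels."""
    classes = [1, 2, 3]
    vals = {c: img[ann_raster == c] for c in classes}
    cents = {c: v.mean() for c, v in vals.items()}
    correct = total = 0
    for c, v in vals.items():
        pred = np.array([min(cents, key=lambda k: abs(cents[k] - x)) for x in v])
        correct += (pred == c).sum()
        total += v.size
    return correct / total


def test_training_accuracy_beats_centroid_oracle(rng):
    img, ann_raster = _three_level_image(rng)
    oracle = _centroid_oracle_accuracy(img, ann_raster)
    assert oracle > 0.95  # the input really is separable
    image = RasterImage(img, 0.1)
    ann = sw.AnnotationSet.from_label_raster(ann_raster)
    clf = sw.train_classifier([image], [ann], seed=0)
    assert clf.metadata["in_sample_accuracy"] > 0.95


def test_missing_class_raises_naming_it(rng):
    img, ann_raster = _three_level_image(rng)
    ann_raster[ann_raster == int(PixelClass.INTERSPACE)] = 0
    ann = sw.AnnotationSet.from_label_raster(ann_raster)
    with pytest.raises(TrainingError, match="INTERSPACE"):
        sw.train_classifier([RasterImage(img, 0.1)], [ann])


def test_training_is_deterministic_and_roundtrips(tmp_path, rng):
    img, ann_raster = _three_level_image(rng)
    image = RasterImage(img, 0.1)
    ann = sw.AnnotationSet.from_label_raster(ann_raster)
    probe = RasterImage(rng.normal(0.5, 0.1, (40, 40)), 0.1)
    c1 = sw.train_classifier([image], [ann], seed=11)
    c2 = sw.train_classifier([image], [ann], seed=11)
    p1 = sw.predict_probabilities(c1, probe).probabilities
    p2 = sw.predict_probabilities(c2, probe).probabilities
    assert np.array_equal(p1, p2)
    c1.save(tmp_path / "clf.model")
    c3 = sw.PixelClassifier.load(tmp_path / "clf.model")
    p3 = sw.predict_probabilities(c3, probe).probabilities
    assert np.array_equal(p1, p3)


def test_probabilities_sum_to_one(trained_classifier, sparse_scene):
    phase, _, _ = sparse_scene
    prob = sw.predict_probabilities(trained_classifier, phase)
    assert np.allclose(prob.probabilities.sum(axis=2), 1.0, atol=1e-6)
    assert prob.probabilities.min() >= 0


def test_pure_class_image_prediction(rng):
    img, ann_raster = _three_level_image(rng)
    image = RasterImage(img, 0.1)
    clf = sw.train_classifier([image], [sw.AnnotationSet.from_label_raster(ann_raster)], seed=0)
    pure_cell = RasterImage(np.full((40, 40), 0.2) + rng.normal(0, 0.01, (40, 40)), 0.1)
    prob = sw.predict_probabilities(clf, pure_cell)
    means = prob.probabilities.mean(axis=(0, 1))
    assert means[0] > means[1] and means[0] > means[2]


def test_empty_image_raises(trained_classifier):
    with pytest.raises(ValueError):
        sw.predict_probabilities(trained_classifier, RasterImage(np.zeros((0, 0)), 0.1))


def _prob_map(pcell):
    rest = (1.0 - pcell) / 2.0
    return sw.ProbabilityMap(np.stack([pcell, rest, rest], axis=2), 0.1)


def test_binarize_saturated_and_subthreshold():
    ones = _prob_map(np.ones((8, 8)))
    assert sw.binarize(ones, 0.5).all()
    low = _prob_map(np.full((8, 8), 0.4))
    assert not sw.binarize(low, 0.5).any()


def test_binarize_hole_filling():
    pcell = np.zeros((20, 20))
    pcell[4:16, 4:16] = 1.0
    pcell[9, 9:12] = 0.0  # 3-px interior hole
    filled = sw.binarize(_prob_map(pcell), 0.5, min_hole_px=10)
    assert filled[9, 9:12].all()
    kept = sw.binarize(_prob_map(pcell), 0.5, min_hole_px=1)
    assert not kept[9, 9:12].any()


@given(st.integers(0, 2**31 - 1), st.floats(0.1, 0.45))
def test_binarize_threshold_monotonicity(seed, delta):
    """Raising the threshold never increases the number of on-pixels."""
    pcell = np.random.default_rng(seed).random((30, 30))
    lo = sw.binarize(_prob_map(pcell), 0.5 - delta)
    hi = sw.binarize(_prob_map(pcell), 0.5 + delta)
    assert hi.sum() <= lo.sum()
    assert not (hi & ~lo).any()


def test_end_to_end_sparse_scene_iou(trained_classifier, sparse_scene):
    """Every ground-truth cell in a sparse scene maps to one mask component with IoU ≥ 0.5."""
    phase, _, truth = sparse_scene
    prob = sw.predict_probabilities(trained_classifier, phase)
    mask = sw.binarize(prob, 0.5, min_hole_px=30)
    labels = sw.label_particles(mask, phase.pixel_size)
    rate, matches = sw.detection_rate(truth, labels, None)
    assert rate == 1.0
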