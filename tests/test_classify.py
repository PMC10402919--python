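"""Pixel classification: features, training, inference, threshold fallback."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from spheroidq import (
    AnnotationSet,
    FeatureSpec,
    ProjectedImage,
    SpheroidScene,
    annotations_from_polygons,
    annotations_from_truth,
    apply_classifier,
    extract_features,
    load_model,
    project,
    refine_regions,
    render_scene,
    save_model,
    threshold_fallback,
    train_classifier,
)
from spheroidq.classify import UNLABELED

from .conftest import NOMINAL_INTENSITY, iou


def _img(pixels):
    pixels = np.asarray(pixels)
    names = [f"CH{i}" for i in range(pixels.shape[0])]
    return ProjectedImage(pixels=pixels, channel_names=names)


def test_feature_count_formula():
    spec = FeatureSpec(sigmas=(1, 2, 4), feature_kinds=("gaussian", "laplacian"))
    img = _img(np.zeros((3, 32, 32)))
    assert extract_features(img, spec).shape == (32, 32, 6 * 3)
    solo = FeatureSpec(
        sigmas=(1, 2, 4), feature_kinds=("gaussian", "laplacian"), use_all_channels=False
    )
    assert extract_features(img, solo).shape == (32, 32, 6)


def test_flat_field_features():
    img = _img(np.full((1, 24, 24), 7.0))
    spec = FeatureSpec(sigmas=(1.0, 2.0), feature_kinds=FeatureSpec().feature_kinds)
    feats = extract_features(img, spec)
    gauss = feats[..., :2]
    assert np.allclose(gauss, 7.0, atol=1e-3)
    rest = feats[..., 2:]  # derivative-based features: zero up to float32 roundoff
    assert np.abs(rest).max() <= 1e-2


def test_gradient_magnitude_matches_finite_difference_oracle():
    """A vertical step edge: gradient magnitude at sigma 1 must peak on the
    edge column and agree with an independent finite-difference computation
    on the smoothed image."""
    step = np.zeros((32, 32))
    step[:, 16:] = 10.0
    img = _img(step[np.newaxis])
    spec = FeatureSpec(sigmas=(1.0,), feature_kinds=("gradient_magnitude",))
    gm = extract_features(img, spec)[..., 0]

    smooth = ndi.gaussian_filter(step, 1.0, mode="reflect")
    gy, gx = np.gradient(smooth)  # central differences: the independent path
    oracle = np.hypot(gy, gx)
    assert np.argmax(gm[16]) in (15, 16)
    assert np.argmax(gm[16]) == np.argmax(oracle[16])
    # central differences slightly smear the peak vs the analytic derivative
    assert gm.max() == pytest.approx(oracle.max(), rel=0.15)
    # edge-response profiles agree to discretization accuracy once
    # peak-normalized (central differences spread mass to neighbor columns)
    assert np.abs(gm / gm.max() - oracle / oracle.max()).max() <= 0.15


def test_oversized_sigma_rejected():
    img = _img(np.zeros((1, 20, 20)))
    with pytest.raises(ValueError, match="sigma"):
        extract_features(img, FeatureSpec(sigmas=(1.0, 16.0)))


def test_feature_spec_validation():
    with pytest.raises(ValueError):
        FeatureSpec(sigmas=(2.0, 1.0))
    with pytest.raises(ValueError):
        FeatureSpec(feature_kinds=())
    with pytest.raises(ValueError):
        FeatureSpec(feature_kinds=("sobel",))


def test_training_is_seed_deterministic(training_pool, default_pair):
    images, truths = training_pool
    ann = annotations_from_truth(truths, fraction=0.01, seed=1)
    m1 = train_classifier(images, ann, seed=42)
    m2 = train_classifier(images, ann, seed=42)
    probe = project(default_pair[0])
    l1, p1 = apply_classifier(m1, probe)
    l2, p2 = apply_classifier(m2, probe)
    assert np.array_equal(l1.labels, l2.labels)
    assert np.array_equal(p1, p2)


def test_heldout_accuracy_on_synthetic_annotations(trained_model):
    """Annotations subsampled from synthetic truth at low relative noise
    must yield a high held-out pixel accuracy."""
    assert trained_model.training_summary["heldout_accuracy"] > 0.95


def test_generalizes_across_scenes_from_same_distribution(training_pool):
    """Labels from one image only; the model must still segment an unseen
    scene drawn from the same distribution (core/outgrowth IoU >= 0.8)."""
    images, truths = training_pool
    ann = annotations_from_truth(truths[:1], fraction=0.02, seed=3)
    model = train_classifier(images[:1], ann, seed=3)
    stack, truth = render_scene(SpheroidScene(seed=777, noise_sigma=8.0))
    raw, _ = apply_classifier(model, project(stack))
    labels = refine_regions(raw)
    assert iou(labels.core_mask, truth.core_mask) >= 0.8
    assert iou(labels.outgrowth_mask, truth.outgrowth_mask) >= 0.8


def test_noiseless_self_training_matches_truth_within_boundary_band(noiseless_pair):
    """Trained on its own truth, the classifier may only disagree with the
    truth partition on a thin (<= 2 px) boundary band."""
    stack, truth = noiseless_pair
    img = project(stack)
    ann = annotations_from_truth([truth], fraction=0.02, seed=5)
    model = train_classifier([img], ann, seed=5)
    raw, _ = apply_classifier(model, img)

    truth_labels = np.zeros(truth.core_mask.shape, dtype=np.uint8)
    truth_labels[truth.core_mask] = 1
    truth_labels[truth.outgrowth_mask] = 2
    disagree = raw.labels != truth_labels
    # distance from any truth class boundary
    boundary = np.zeros_like(disagree)
    for code in (0, 1, 2):
        m = truth_labels == code
        boundary |= m ^ ndi.binary_erosion(m)
    dist = ndi.distance_transform_edt(~boundary)
    assert not disagree.any() or dist[disagree].max() <= 2.0


def test_probability_maps_normalized(trained_model, default_pair):
    _, prob = apply_classifier(trained_model, project(default_pair[0]))
    assert prob.shape[0] == 3
    assert np.abs(prob.sum(axis=0) - 1.0).max() <= 1e-6


def test_all_zero_image_is_background(trained_model):
    img = ProjectedImage(
        pixels=np.zeros((3, 48, 48), dtype=np.uint16),
        channel_names=["FLS", "EC", "MACROPHAGE"],
    )
    labels, _ = apply_classifier(trained_model, img)
    assert (labels.labels == 0).all()


def test_channel_mismatch_rejected(trained_model):
    img = ProjectedImage(pixels=np.zeros((2, 32, 32)), channel_names=["A", "B"])
    with pytest.raises(ValueError, match="channel"):
        apply_classifier(trained_model, img)


def test_missing_class_error_names_it(training_pool):
    images, truths = training_pool
    ann = annotations_from_truth(truths, fraction=0.01, seed=1)
    for m in ann.masks:
        m[m == 2] = UNLABELED  # wipe all outgrowth labels
    with pytest.raises(ValueError, match="outgrowth"):
        train_classifier(images, ann, seed=0)


def test_sparse_class_warning_recorded(training_pool):
    images, truths = training_pool
    ann = annotations_from_truth(truths[:1], fraction=0.02, seed=2)
    mask = ann.masks[0]
    rr, cc = np.nonzero(mask == 1)
    mask[rr[5:], cc[5:]] = UNLABELED  # leave only 5 core pixels
    with pytest.warns(UserWarning, match="core"):
        model = train_classifier(images[:1], AnnotationSet([mask]), seed=0)
    assert any("core" in w for w in model.training_summary["warnings"])


def test_threshold_zero_recovers_noiseless_cell_mask_exactly(noiseless_pair):
    stack, truth = noiseless_pair
    img = project(stack)
    res = threshold_fallback(img, threshold=0.0)
    assert np.array_equal(res.cell_mask, truth.core_mask | truth.outgrowth_mask)
    assert res.qc_flags == []


def test_half_intensity_threshold_misses_only_soft_fringe(noiseless_pair):
    stack, truth = noiseless_pair
    img = project(stack)
    union = truth.core_mask | truth.outgrowth_mask
    res = threshold_fallback(img, threshold=0.5 * NOMINAL_INTENSITY)
    diff = res.cell_mask ^ union
    assert union[diff].all()  # only losses, no spurious pixels
    boundary = union ^ ndi.binary_erosion(union)
    dist = ndi.distance_transform_edt(~boundary)
    assert not diff.any() or dist[diff].max() <= 1.5


def test_otsu_matches_brute_force_between_class_variance_search():
    rng = np.random.default_rng(0)
    lo = rng.normal(40, 6, 3000)
    hi = rng.normal(180, 12, 2000)
    pixels = np.clip(np.concatenate([lo, hi]), 0, 255).reshape(1, 50, 100)
    img = _img(pixels)
    res = threshold_fallback(img, threshold="otsu")

    # exhaustive search over candidate thresholds maximizing sigma_b^2
    flat = pixels.ravel()
    candidates = np.unique(np.round(flat))
    best_t, best_v = None, -1.0
    for t in candidates:
        g0, g1 = flat[flat <= t], flat[flat > t]
        if g0.size == 0 or g1.size == 0:
            continue
        w0, w1 = g0.size / flat.size, g1.size / flat.size
        v = w0 * w1 * (g0.mean() - g1.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    assert 40 < res.threshold < 180  # between the two modes
    assert abs(res.threshold - best_t) <= (flat.max() - flat.min()) / 256


def test_threshold_above_max_flags_empty_mask(noiseless_pair):
    img = project(noiseless_pair[0])
    res = threshold_fallback(img, threshold=1e9)
    assert not res.cell_mask.any()
    assert "empty cell mask" in res.qc_flags


def test_polygon_annotations_rasterize():
    polys = [
        {"class": "core", "vertices": [[2, 2], [2, 8], [8, 8], [8, 2]]},
        {"class": "background", "vertices": [[12, 12], [12, 15], [15, 15], [15, 12]]},
    ]
    mask = annotations_from_polygons(polys, (20, 20))
    assert mask[5, 5] == 1
    assert mask[13, 13] == 0
    assert mask[0, 0] == UNLABELED
    with pytest.raises(ValueError, match="unknown class"):
        annotations_from_polygons([{"class": "halo", "vertices": [[0, 0]]}], (5, 5))


def test_model_archive_round_trip(tmp_path, trained_model, default_pair):
    path = tmp_path / "model.bin"
    save_model(trained_model, path)
    back = load_model(path)
    assert back.feature_spec == trained_model.feature_spec
    assert back.class_order == trained_model.class_order
    probe = project(default_pair[0])
    l1, _ = apply_classifier(trained_model, probe)
    l2, _ = apply_classifier(back, probe)
    assert np.array_equal(l1.labels, l2.labels)
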