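"""Trainable pixel classification of projected spheroid images.

Each pixel of a projected multi-channel image is mapped to one of three
semantic classes — background, core, or outgrowth — by a seeded
random-forest ensemble trained on sparse user annotations, using multiscale
intensity, edge and texture features.  A deterministic global-threshold
fallback is provided for the classifier-free workflow (the core/outgrowth
split is then derived morphologically, see :mod:`spheroidq.regions`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import feature as skfeature
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .regions import CLASS_NAMES, LABEL_BACKGROUND, LABEL_CORE, LABEL_OUTGROWTH, RegionLabelMap
from .stacks import ProjectedImage

UNLABELED = -1

FEATURE_KINDS = (
    "gaussian",
    "gradient_magnitude",
    "laplacian",
    "structure_tensor_eigenvalues",
    "difference_of_gaussians",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Multiscale per-pixel feature configuration.

    One feature per (channel, kind, sigma); ``structure_tensor_eigenvalues``
    contributes its largest eigenvalue.  With ``use_all_channels=False`` the
    channels are summed into a single composite before feature extraction.
    """

    sigmas: tuple = (1.0, 2.0, 4.0, 8.0)
    feature_kinds: tuple = ("gaussian", "gradient_magnitude", "laplacian")
    use_all_channels: bool = True

    def __post_init__(self):
        if not self.feature_kinds:
            raise ValueError("feature_kinds must be non-empty")
        unknown = set(self.feature_kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds {sorted(unknown)}")
        s = tuple(float(x) for x in self.sigmas)
        if not s or any(x <= 0 for x in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("sigmas must be strictly increasing and > 0")
        object.__setattr__(self, "sigmas", s)
        object.__setattr__(self, "feature_kinds", tuple(self.feature_kinds))

    def n_features(self, n_channels: int) -> int:
        ch = n_channels if self.use_all_channels else 1
        return len(self.sigmas) * len(self.feature_kinds) * ch

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigmas": list(self.sigmas),
                "feature_kinds": list(self.feature_kinds),
                "use_all_channels": self.use_all_channels,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureSpec":
        d = json.loads(s)
        return cls(
            sigmas=tuple(d["sigmas"]),
            feature_kinds=tuple(d["feature_kinds"]),
            use_all_channels=bool(d["use_all_channels"]),
        )


def _single_channel_features(ch: np.ndarray, spec: FeatureSpec) -> list:
    feats = []
    for kind in spec.feature_kinds:
        for sigma in spec.sigmas:
            if kind == "gaussian":
                f = ndi.gaussian_filter(ch, sigma, mode="reflect")
            elif kind == "gradient_magnitude":
                f = ndi.gaussian_gradient_magnitude(ch, sigma, mode="reflect")
            elif kind == "laplacian":
                f = ndi.gaussian_laplace(ch, sigma, mode="reflect")
            elif kind == "difference_of_gaussians":
                f = ndi.gaussian_filter(ch, sigma, mode="reflect") - ndi.gaussian_filter(
                    ch, 1.6 * sigma, mode="reflect"
                )
            else:  # structure_tensor_eigenvalues: largest eigenvalue
                axx, axy, ayy = skfeature.structure_tensor(
                    ch, sigma=sigma, mode="reflect", order="xy"
                )
                eig = skfeature.structure_tensor_eigenvalues((axx, axy, ayy))
                f = eig[0]
            feats.append(f.astype(np.float32))
    return feats


def extract_features(img: ProjectedImage, spec: FeatureSpec) -> np.ndarray:
    """Per-pixel feature stack of shape (rows, cols, n_features).

    Borders are handled by reflection; the computation is deterministic.
    Feature order is channel-major, then kind, then sigma.
    """
    h, w = img.shape
    if max(spec.sigmas) > min(h, w) / 2:
        raise ValueError(
            f"sigma {max(spec.sigmas)} exceeds half the image extent {min(h, w) / 2}"
        )
    if spec.use_all_channels:
        channels = [img.pixels[c].astype(np.float32) for c in range(img.n_channels)]
    else:
        channels = [img.pixels.astype(np.float32).sum(axis=0)]
    feats: list = []
    for ch in channels:
        feats.extend(_single_channel_features(ch, spec))
    return np.stack(feats, axis=-1)


@dataclass
class AnnotationSet:
    """Sparse per-image label masks for classifier training.

    Each mask is an integer array matching its image's (row, col) shape, with
    ``-1`` for unlabeled pixels and class codes 0/1/2 for
    background/core/outgrowth.  ``provenance`` records where each mask's
    strokes came from.
    """

    masks: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if not self.provenance:
            self.provenance = ["unknown"] * len(self.masks)
        if len(self.provenance) != len(self.masks):
            raise ValueError("provenance length must match masks")
        for m in self.masks:
            vals = np.unique(np.asarray(m))
            bad = set(vals.tolist()) - {UNLABELED, LABEL_BACKGROUND, LABEL_CORE, LABEL_OUTGROWTH}
            if bad:
                raise ValueError(f"annotation mask contains invalid labels {sorted(bad)}")

    def class_counts(self) -> dict:
        counts = {name: 0 for name in CLASS_NAMES}
        for m in self.masks:
            m = np.asarray(m)
            for code, name in enumerate(CLASS_NAMES):
                counts[name] += int((m == code).sum())
        return counts


def annotations_from_truth(truths, fraction: float = 0.01, seed: int = 0) -> AnnotationSet:
    """Subsample ground-truth masks into sparse annotations (for validation)."""
    rng = np.random.default_rng(seed)
    masks = []
    for truth in truths:
        full = np.full(truth.core_mask.shape, UNLABELED, dtype=np.int16)
        full[truth.background_mask] = LABEL_BACKGROUND
        full[truth.core_mask] = LABEL_CORE
        full[truth.outgrowth_mask] = LABEL_OUTGROWTH
        keep = rng.random(full.shape) < fraction
        mask = np.where(keep, full, UNLABELED).astype(np.int16)
        # guarantee at least one labeled pixel per present class
        for code in (LABEL_BACKGROUND, LABEL_CORE, LABEL_OUTGROWTH):
            if (full == code).any() and not (mask == code).any():
                rr, cc = np.nonzero(full == code)
                i = rng.integers(0, rr.size)
                mask[rr[i], cc[i]] = code
        masks.append(mask)
    return AnnotationSet(masks, provenance=["subsampled ground truth"] * len(masks))


def annotations_from_polygons(polygons, image_shape) -> np.ndarray:
    """Rasterize polygon annotations into a sparse label mask.

    ``polygons`` is a list of ``{"class": name, "vertices": [[r, c], ...]}``
    dicts (0-based pixel coordinates), or a path to a JSON file of the same.
    """
    if isinstance(polygons, (str, Path)):
        polygons = json.loads(Path(polygons).read_text())
    mask = np.full(image_shape, UNLABELED, dtype=np.int16)
    for poly in polygons:
        name = poly["class"]
        if name not in CLASS_NAMES:
            raise ValueError(f"unknown class {name!r}; expected one of {CLASS_NAMES}")
        code = CLASS_NAMES.index(name)
        verts = np.asarray(poly["vertices"], dtype=float)
        rr, cc = skdraw.polygon(verts[:, 0], verts[:, 1], shape=image_shape)
        mask[rr, cc] = code
    return mask


@dataclass
class PixelClassifierModel:
    """A fitted pixel classifier: feature spec + seeded ensemble state."""

    feature_spec: FeatureSpec
    estimator: RandomForestClassifier
    class_order: tuple = tuple(CLASS_NAMES)
    training_seed: int = 0
    n_channels: int = 3
    training_summary: dict = field(default_factory=dict)


MIN_LABELED_PER_CLASS = 50


def train_classifier(
    images: list,
    annotations: AnnotationSet,
    spec: FeatureSpec | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> PixelClassifierModel:
    """Fit a seeded random forest on the labeled pixels of annotated images.

    Classes are balanced by weighting; the out-of-bag score over the labeled
    pixels is recorded in ``training_summary`` as the held-out accuracy
    estimate.  A class with no labeled pixel anywhere is an error; a class
    with fewer than ``MIN_LABELED_PER_CLASS`` pixels is recorded as a warning.
    """
    spec = spec or FeatureSpec()
    if len(images) != len(annotations.masks):
        raise ValueError("one annotation mask per image required")
    counts = annotations.class_counts()
    for name, n in counts.items():
        if n == 0:
            raise ValueError(f"class {name!r} has no labeled pixels")
    summary: dict = {"labeled_per_class": counts, "warnings": []}
    for name, n in counts.items():
        if n < MIN_LABELED_PER_CLASS:
            msg = f"class {name!r} has only {n} labeled pixels (< {MIN_LABELED_PER_CLASS})"
            summary["warnings"].append(msg)
            warnings.warn(msg, stacklevel=2)

    xs, ys = [], []
    n_channels = images[0].n_channels
    for img, mask in zip(images, annotations.masks):
        mask = np.asarray(mask)
        if mask.shape != img.shape:
            raise ValueError("annotation mask shape does not match its image")
        if img.n_channels != n_channels:
            raise ValueError("all training images must share a channel count")
        labeled = mask != UNLABELED
        feats = extract_features(img, spec)
        xs.append(feats[labeled])
        ys.append(mask[labeled])
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    est = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced",
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny annotation sets can leave some samples out of no bootstrap
        warnings.simplefilter("ignore", UserWarning)
        est.fit(x, y)
    summary["heldout_accuracy"] = float(getattr(est, "oob_score_", np.nan))
    return PixelClassifierModel(
        feature_spec=spec,
        estimator=est,
        class_order=tuple(CLASS_NAMES),
        training_seed=seed,
        n_channels=n_channels,
        training_summary=summary,
    )


def apply_classifier(model: PixelClassifierModel, img: ProjectedImage) -> tuple:
    """Classify every pixel; returns (RegionLabelMap, probability maps).

    Probability maps have shape (3, rows, cols) ordered as
    background/core/outgrowth and sum to 1 per pixel.  Inference is
    deterministic for a fixed model.
    """
    expected = model.n_channels if model.feature_spec.use_all_channels else None
    if expected is not None and img.n_channels != expected:
        raise ValueError(
            f"channel mismatch: model expects {expected} channels, "
            f"image has {img.n_channels}"
        )
    feats = extract_features(img, model.feature_spec)
    h, w, f = feats.shape
    proba = model.estimator.predict_proba(feats.reshape(-1, f))
    full = np.zeros((h * w, len(CLASS_NAMES)), dtype=np.float64)
    for j, code in enumerate(model.estimator.classes_):
        full[:, int(code)] = proba[:, j]
    prob_maps = full.T.reshape(len(CLASS_NAMES), h, w)
    labels = np.argmax(prob_maps, axis=0).astype(np.uint8)
    return (
        RegionLabelMap(labels=labels, provenance="classifier", qc_flags=[]),
        prob_maps,
    )


@dataclass
class ThresholdResult:
    """Cell/background split from a global intensity threshold.

    The core/outgrowth discrimination is deferred to
    :func:`spheroidq.regions.derive_regions_from_cellmask`.
    """

    cell_mask: np.ndarray
    threshold: float
    qc_flags: list


def threshold_fallback(
    img: ProjectedImage, threshold: float | str = "otsu"
) -> ThresholdResult:
    """Deterministic classifier-free cell mask from the composite intensity.

    ``threshold`` is either a fixed intensity value or ``"otsu"``.  An empty
    cell mask is flagged, not an error.
    """
    composite = img.pixels.astype(np.float64).sum(axis=0)
    if threshold == "otsu":
        thr = float(threshold_otsu(composite))
    else:
        thr = float(threshold)
    mask = composite > thr
    flags = [] if mask.any() else ["empty cell mask"]
    return ThresholdResult(cell_mask=mask, threshold=thr, qc_flags=flags)


def segment_by_threshold(img: ProjectedImage, threshold="otsu", config=None) -> RegionLabelMap:
    """Threshold fallback composed with morphological region derivation."""
    from .regions import derive_regions_from_cellmask

    res = threshold_fallback(img, threshold)
    labels = derive_regions_from_cellmask(res.cell_mask, config)
    labels.provenance = "threshold_fallback"
    labels.qc_flags = res.qc_flags + labels.qc_flags
    return labels


def save_model(model: PixelClassifierModel, path) -> None:
    """Serialize a model (feature spec as JSON + fitted state) to one archive."""
    payload = {
        "feature_spec_json": model.feature_spec.to_json(),
        "estimator": model.estimator,
        "class_order": list(model.class_order),
        "training_seed": model.training_seed,
        "n_channels": model.n_channels,
        "training_summary": model.training_summary,
    }
    joblib.dump(payload, path)


def load_model(path) -> PixelClassifierModel:
    payload = joblib.load(path)
    return PixelClassifierModel(
        feature_spec=FeatureSpec.from_json(payload["feature_spec_json"]),
        estimator=payload["estimator"],
        class_order=tuple(payload["class_order"]),
        training_seed=payload["training_seed"],
        n_channels=payload["n_channels"],
        training_summary=payload["training_summary"],
    )
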