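"""Classifier training from sparse annotations and dense prediction.

Training touches only the planes that carry annotations, and for local
extractors only the bounding crop of the annotated pixels padded by the
extractor's context margin — so the sampled feature rows are bit-identical
to full-image extraction while skipping almost all of the image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .core import (
    AnnotationMask,
    ExtractorSpec,
    ImageStack,
    NormalizationConfig,
    TrainedModel,
    normalize_stack,
)
from .features import FeatureExtractor, create_extractor

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("gradient_boosted_trees", "random_forest")


@dataclass
class TrainingSet:
    """Feature rows for annotated pixels, ordered by (plane, y, x)."""

    X: np.ndarray  # (n_rows, F)
    y: np.ndarray  # (n_rows,)
    coords: np.ndarray  # (n_rows, 3) plane, y, x
    extractor: ExtractorSpec = None  # type: ignore[assignment]
    n_image_channels: int = 1

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.coords.shape[0]:
            raise ValueError("X, y and coords must have matching row counts")
        if np.any(self.y == 0):
            raise ValueError("class 0 (unannotated) cannot appear in training rows")

    @property
    def classes(self) -> list[int]:
        return [int(c) for c in np.unique(self.y)]


def sample_training_set(
    stack: ImageStack,
    ann: AnnotationMask,
    spec: "ExtractorSpec | FeatureExtractor",
    use_crops: bool = True,
) -> TrainingSet:
    """Extract feature rows for every annotated pixel.

    Local extractors run on annotation bounding crops padded by their context
    margin; whole-image-context extractors run on the full planes that carry
    annotations.  ``use_crops=False`` forces full-plane extraction (used to
    verify crop/full equivalence).
    """
    ann.check_against(stack)
    classes = ann.classes()
    if len(classes) < 2:
        raise ValueError(
            f"training requires >= 2 annotated classes, found {classes or 'none'}"
        )
    ext = spec if isinstance(spec, FeatureExtractor) else create_extractor(spec)
    spec_obj = ext.spec

    if spec_obj.kind == "multiprojection":
        return _sample_multiprojection(stack, ann, ext)

    margin = ext.context_margin()
    rows_X: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    rows_c: list[np.ndarray] = []
    h, w = stack.spatial_shape
    for p in range(stack.n_planes):
        labels = ann.plane(p)
        ys, xs = np.nonzero(labels)  # row-major: sorted by (y, x)
        if ys.size == 0:
            continue
        plane = stack.plane(p)
        if margin is None or not use_crops:
            feats = ext.extract(plane)
            rows_X.append(feats[:, ys, xs].T)
        else:
            y0 = max(int(ys.min()) - margin, 0)
            y1 = min(int(ys.max()) + 1 + margin, h)
            x0 = max(int(xs.min()) - margin, 0)
            x1 = min(int(xs.max()) + 1 + margin, w)
            feats = ext.extract(plane[:, y0:y1, x0:x1])
            rows_X.append(feats[:, ys - y0, xs - x0].T)
        rows_y.append(labels[ys, xs].astype(np.int64))
        rows_c.append(np.column_stack([np.full(ys.size, p), ys, xs]))
    X = np.concatenate(rows_X, axis=0)
    expected = ext.n_channels(stack.n_channels)
    if X.shape[1] != expected:
        raise AssertionError(
            f"extractor produced {X.shape[1]} channels, declared {expected}"
        )
    return TrainingSet(
        X=X,
        y=np.concatenate(rows_y),
        coords=np.concatenate(rows_c, axis=0),
        extractor=spec_obj,
        n_image_channels=stack.n_channels,
    )


def _sample_multiprojection(
    stack: ImageStack, ann: AnnotationMask, ext: FeatureExtractor
) -> TrainingSet:
    volume = np.stack([stack.plane(p) for p in range(stack.n_planes)], axis=1)
    feats = ext.extract_volume(volume)  # (F, Z, Y, X)
    labels = ann.labels if ann.labels.ndim == 3 else ann.labels[np.newaxis]
    zs, ys, xs = np.nonzero(labels)
    return TrainingSet(
        X=feats[:, zs, ys, xs].T,
        y=labels[zs, ys, xs].astype(np.int64),
        coords=np.column_stack([zs, ys, xs]),
        extractor=ext.spec,
        n_image_channels=stack.n_channels,
    )


def train_classifier(
    ts: TrainingSet,
    kind: str = "gradient_boosted_trees",
    seed: int = 0,
    normalization: NormalizationConfig | None = None,
    balanced: bool = False,
) -> TrainedModel:
    """Fit a lightweight classifier on a TrainingSet.

    Deterministic given ``seed``.  ``gradient_boosted_trees`` is the default
    family; ``random_forest`` is the alternative.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    if len(ts.classes) < 2:
        raise ValueError("training requires >= 2 classes")
    if np.all(ts.X == ts.X[0]) and len(ts.classes) > 1:
        logger.warning(
            "feature matrix is constant but labels conflict; the classifier "
            "will fit with ties"
        )
    if kind == "gradient_boosted_trees":
        from sklearn.ensemble import HistGradientBoostingClassifier

        clf = HistGradientBoostingClassifier(
            random_state=seed,
            class_weight="balanced" if balanced else None,
        )
    else:
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=100,
            random_state=seed,
            n_jobs=1,
            class_weight="balanced" if balanced else None,
        )
    clf.fit(ts.X, ts.y)
    return TrainedModel(
        classifier=clf,
        extractor=ts.extractor,
        normalization=normalization or NormalizationConfig(),
        classes=ts.classes,
        n_channels=ts.n_image_channels,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _as_plane(plane: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim == 2:
        plane = plane[np.newaxis]
    return plane


def _normalize_plane(plane: np.ndarray, cfg: NormalizationConfig) -> np.ndarray:
    if cfg.mode == "none":
        return plane
    stack = ImageStack(data=plane, axes=("channel", "y", "x"))
    return normalize_stack(stack, cfg).data


def predict_features(features: np.ndarray, model: TrainedModel):
    """Classify a (F, H, W) feature array -> (labels (H, W), proba (K, H, W)).

    Argmax ties break toward the lower class id (classes are sorted; numpy
    argmax returns the first maximum).
    """
    f, h, w = features.shape
    proba = model.classifier.predict_proba(features.reshape(f, h * w).T)
    idx = np.argmax(proba, axis=1)
    labels = np.asarray(model.classes, dtype=np.int32)[idx].reshape(h, w)
    return labels, proba.T.reshape(len(model.classes), h, w)


def predict_image(
    plane: np.ndarray,
    model: TrainedModel,
    return_proba: bool = False,
    normalized: bool = False,
):
    """Predict a dense class map for one (C, H, W) or (H, W) plane."""
    plane = _as_plane(plane)
    model.check_channels(plane.shape[0])
    if not normalized:
        plane = _normalize_plane(plane, model.normalization)
    ext = create_extractor(model.extractor)
    labels, proba = predict_features(ext.extract(plane), model)
    return (labels, proba) if return_proba else labels


def predict_stack(
    stack: ImageStack,
    model: TrainedModel,
    planes: Sequence[int] | None = None,
) -> np.ndarray:
    """Predict a label map per selected plane (default: all planes).

    Planes are processed one at a time, so peak memory stays at one plane's
    features even for larger-than-memory (e.g. zarr-backed) stacks.
    """
    model.check_channels(stack.n_channels)
    selection = list(range(stack.n_planes)) if planes is None else list(planes)
    if not selection:
        raise ValueError("empty plane selection")
    for p in selection:
        if not 0 <= p < stack.n_planes:
            raise IndexError(f"plane {p} out of range")
    if model.normalization.mode == "per_stack":
        stack = normalize_stack(stack, model.normalization)
        norm_done = True
    else:
        norm_done = model.normalization.mode == "none"
    ext = create_extractor(model.extractor)

    if model.extractor.kind == "multiprojection":
        volume = np.stack([stack.plane(p) for p in range(stack.n_planes)], axis=1)
        feats = ext.extract_volume(volume)
        out = []
        for p in selection:
            labels, _ = predict_features(feats[:, p], model)
            out.append(labels)
        return np.stack(out)

    out_planes = []
    for p in selection:
        plane = stack.plane(p)
        if not norm_done:
            plane = _normalize_plane(plane, model.normalization)
        labels, _ = predict_features(ext.extract(plane), model)
        out_planes.append(labels)
    return np.stack(out_planes)


def smooth_labels_majority(labels: np.ndarray, footprint_radius: int = 1) -> np.ndarray:
    """Replace each pixel by the modal label in its (2r+1)^2 window.

    Ties keep the center pixel's label when it participates in the tie;
    otherwise the lowest tied label wins.  Windows are clipped at borders.
    """
    if footprint_radius < 1:
        raise ValueError("footprint_radius must be >= 1")
    labels = np.asarray(labels)
    vals = np.unique(labels)
    if vals.size == 1:
        return labels.copy()
    k = 2 * footprint_radius + 1
    kernel = np.ones((k, k))
    counts = np.stack(
        [
            ndi.correlate((labels == v).astype(np.float64), kernel, mode="constant")
            for v in vals
        ]
    )
    counts = np.rint(counts).astype(np.int64)
    best_idx = np.argmax(counts, axis=0)  # first max -> lowest label
    max_count = np.take_along_axis(counts, best_idx[np.newaxis], axis=0)[0]
    center_idx = np.searchsorted(vals, labels)
    center_count = np.take_along_axis(counts, center_idx[np.newaxis], axis=0)[0]
    out = vals[best_idx]
    keep = center_count == max_count
    out[keep] = labels[keep]
    return out.astype(labels.dtype)


def predict_with_downscale(
    plane: np.ndarray,
    model: TrainedModel,
    factor: int = 2,
    majority_radius: int | None = 1,
) -> np.ndarray:
    """Downscale (bilinear), predict, upscale labels (nearest), then smooth
    with a majority filter.  ``factor=1`` with ``majority_radius=None`` is
    exactly :func:`predict_image`."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    plane = _as_plane(plane)
    h, w = plane.shape[1:]
    if factor > min(h, w):
        raise ValueError(f"downscale factor {factor} exceeds image side {min(h, w)}")
    if factor == 1:
        labels = predict_image(plane, model)
    else:
        small = np.stack(
            [
                resize(ch, (h // factor, w // factor), order=1, mode="reflect",
                       preserve_range=True, anti_aliasing=False)
                for ch in plane
            ]
        )
        small_labels = predict_image(small, model)
        labels = resize(
            small_labels, (h, w), order=0, mode="edge", preserve_range=True,
            anti_aliasing=False
        ).astype(small_labels.dtype)
    if majority_radius:
        labels = smooth_labels_majority(labels, majority_radius)
    return labels
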