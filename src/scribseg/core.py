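"""Shared domain types, intensity normalization, and model persistence.

Conventions used throughout:

* An :class:`ImageStack` wraps an n-D array whose axes carry explicit roles
  drawn from ``{"plane", "channel", "y", "x"}``.  ``plane`` covers either z
  or time; there is at most one of each non-spatial role.
* Label images (scribbles, ground truth, predictions) are integer arrays over
  the ``(plane, y, x)`` grid, with 0 meaning "unannotated".
* Planes handed to feature extractors are always ``(C, H, W)`` float arrays.
"""

from __future__ import annotations

import hashlib
import io
import json
import pickle
import zipfile
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AXIS_ROLES",
    "ImageStack",
    "AnnotationMask",
    "FeatureMap",
    "ExtractorSpec",
    "NormalizationConfig",
    "TrainedModel",
    "normalize_stack",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

AXIS_ROLES = ("plane", "channel", "y", "x")

MODEL_FORMAT_VERSION = 1

EXTRACTOR_KINDS = (
    "gaussian_baseline",
    "filterbank",
    "cnn_pyramid",
    "vit_patch",
    "combined",
    "multiprojection",
)


class ModelFormatError(RuntimeError):
    """Raised when a persisted model archive is malformed or unsupported."""


@dataclass(frozen=True)
class ImageStack:
    """n-D intensity data with declared axis roles.

    Parameters
    ----------
    data:
        Numeric array; one dimension per entry in ``axes``.
    axes:
        Ordered roles, a permutation-free subset of
        ``("plane", "channel", "y", "x")`` containing exactly one ``y`` and
        one ``x``.
    """

    data: np.ndarray
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data) if not hasattr(self.data, "ndim") else self.data
        object.__setattr__(self, "data", data)
        axes = tuple(self.axes)
        object.__setattr__(self, "axes", axes)
        if data.ndim != len(axes):
            raise ValueError(
                f"data has {data.ndim} dimensions but {len(axes)} axis roles given"
            )
        if len(set(axes)) != len(axes):
            raise ValueError(f"axis roles must be unique, got {axes}")
        for role in axes:
            if role not in AXIS_ROLES:
                raise ValueError(f"unknown axis role {role!r}")
        if axes.count("y") != 1 or axes.count("x") != 1:
            raise ValueError("exactly one y and one x axis required")
        if any(s < 1 for s in data.shape):
            raise ValueError("all axis extents must be >= 1")

    # -- geometry -------------------------------------------------------
    def axis_index(self, role: str) -> int | None:
        return self.axes.index(role) if role in self.axes else None

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return (
            self.data.shape[self.axes.index("y")],
            self.data.shape[self.axes.index("x")],
        )

    @property
    def n_planes(self) -> int:
        i = self.axis_index("plane")
        return 1 if i is None else self.data.shape[i]

    @property
    def n_channels(self) -> int:
        i = self.axis_index("channel")
        return 1 if i is None else self.data.shape[i]

    @property
    def pixel_kind(self) -> str:
        return "integer" if np.issubdtype(np.asarray(self.data[(0,) * self.data.ndim]).dtype, np.integer) else "float"

    def plane(self, index: int) -> np.ndarray:
        """Return plane ``index`` as a float64 ``(C, H, W)`` array.

        Works for lazily-indexed containers (e.g. zarr arrays) without
        materializing other planes.
        """
        if not 0 <= index < self.n_planes:
            raise IndexError(f"plane {index} out of range (n_planes={self.n_planes})")
        sel: list[Any] = [slice(None)] * len(self.axes)
        pi = self.axis_index("plane")
        if pi is not None:
            sel[pi] = index
        arr = np.asarray(self.data[tuple(sel)], dtype=np.float64)
        axes = [a for a in self.axes if a != "plane"]
        if "channel" not in axes:
            arr = arr[np.newaxis]
            axes = ["channel"] + axes
        order = [axes.index(a) for a in ("channel", "y", "x")]
        return np.transpose(arr, order)

    def planes(self) -> Iterator[np.ndarray]:
        for i in range(self.n_planes):
            yield self.plane(i)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(data=data, axes=self.axes)


@dataclass(frozen=True)
class AnnotationMask:
    """Sparse integer scribble labels on a stack's ``(plane, y, x)`` grid."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim not in (2, 3):
            raise ValueError("annotation labels must be 2D (y,x) or 3D (plane,y,x)")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("annotation labels must be an integer array")
        if labels.min(initial=0) < 0:
            raise ValueError("annotation labels must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def n_planes(self) -> int:
        return 1 if self.labels.ndim == 2 else self.labels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return tuple(self.labels.shape[-2:])  # type: ignore[return-value]

    def plane(self, index: int) -> np.ndarray:
        return self.labels if self.labels.ndim == 2 else self.labels[index]

    def classes(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def check_against(self, stack: ImageStack) -> None:
        if self.spatial_shape != stack.spatial_shape:
            raise ValueError(
                f"annotation spatial shape {self.spatial_shape} != "
                f"stack spatial shape {stack.spatial_shape}"
            )
        if self.n_planes != stack.n_planes:
            raise ValueError(
                f"annotation has {self.n_planes} planes, stack has {stack.n_planes}"
            )


@dataclass(frozen=True)
class FeatureMap:
    """Per-pixel feature vectors: ``values`` has shape ``(F, spatial...)``."""

    values: np.ndarray
    fingerprint: str
    scale: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[1:]


def _canonical_params(params: Mapping[str, Any]) -> Any:
    def conv(v: Any) -> Any:
        if isinstance(v, Mapping):
            return {k: conv(v[k]) for k in sorted(v)}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return conv(dict(params))


@dataclass(frozen=True)
class ExtractorSpec:
    """Declarative description of a feature extractor.

    ``params`` is kind-specific (sigmas; pyramid scales/layers; patch size and
    embedding width; child specs for ``combined``/``multiprojection``).
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)
    whole_image_context: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", _canonical_params(self.params))

    def fingerprint(self) -> str:
        blob = json.dumps(
            {"kind": self.kind, "params": self.params, "wic": self.whole_image_context},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "params": self.params,
            "whole_image_context": self.whole_image_context,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExtractorSpec":
        return cls(
            kind=d["kind"],
            params=d.get("params", {}),
            whole_image_context=bool(d.get("whole_image_context", False)),
        )


@dataclass(frozen=True)
class NormalizationConfig:
    """Percentile-rescale normalization, scoped per plane or per stack.

    Statistics are computed per channel in both modes (configurable pooling is
    out of scope; per-channel is the default behaviour).
    """

    mode: str = "none"  # none | per_plane | per_stack
    percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "per_plane", "per_stack"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        object.__setattr__(self, "percentiles", (float(lo), float(hi)))

    def to_dict(self) -> dict[str, Any]:
        return {"mode": self.mode, "percentiles": list(self.percentiles)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NormalizationConfig":
        return cls(mode=d["mode"], percentiles=tuple(d["percentiles"]))


def _rescale(block: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(block, dtype=np.float64)
    out = (block.astype(np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def normalize_stack(stack: ImageStack, cfg: NormalizationConfig) -> ImageStack:
    """Rescale intensities so the configured percentiles map to [0, 1].

    ``per_plane`` rescales every plane independently; ``per_stack`` computes
    one percentile pair over all planes jointly.  Statistics are per channel.
    Constant scopes (low percentile == high percentile) map to all-zeros —
    never NaN or Inf.
    """
    if cfg.mode == "none":
        return stack
    lo_p, hi_p = cfg.percentiles
    data = np.asarray(stack.data, dtype=np.float64)
    pi = stack.axis_index("plane")
    ci = stack.axis_index("channel")

    out = np.empty_like(data)
    n_channels = stack.n_channels

    def channel_slices(index: "int | None", n: int):
        if index is None:
            yield (slice(None),) * data.ndim
        else:
            for c in range(n):
                sel = [slice(None)] * data.ndim
                sel[index] = c
                yield tuple(sel)

    for csel in channel_slices(ci, n_channels):
        block = data[csel]
        if cfg.mode == "per_stack" or pi is None:
            lo, hi = np.percentile(block, [lo_p, hi_p])
            out[csel] = _rescale(block, float(lo), float(hi))
        else:
            # plane axis position within the channel-sliced view
            drop = 0 if ci is None else int(pi > ci)
            plane_ax = pi - drop
            res = np.empty_like(block)
            for p in range(block.shape[plane_ax]):
                psel = [slice(None)] * block.ndim
                psel[plane_ax] = p
                sub = block[tuple(psel)]
                lo, hi = np.percentile(sub, [lo_p, hi_p])
                res[tuple(psel)] = _rescale(sub, float(lo), float(hi))
            out[csel] = res
    return stack.with_data(out)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce predictions."""

    classifier: Any
    extractor: ExtractorSpec
    normalization: NormalizationConfig
    classes: list[int]
    n_channels: int
    seed: int | None = None
    format_version: int = MODEL_FORMAT_VERSION
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = sorted(int(c) for c in self.classes)
        if len(self.classes) < 2:
            raise ValueError("a trained model needs at least 2 classes")
        if 0 in self.classes:
            raise ValueError("class 0 is reserved for unannotated pixels")

    def check_channels(self, n_channels: int) -> None:
        if n_channels != self.n_channels:
            raise ValueError(
                f"input has {n_channels} channels but the model was trained "
                f"with {self.n_channels}"
            )

    def manifest(self) -> dict[str, Any]:
        return {
            "format_version": self.format_version,
            "extractor": self.extractor.to_dict(),
            "normalization": self.normalization.to_dict(),
            "classes": self.classes,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "provenance": self.provenance,
        }


def save_model(model: TrainedModel, path) -> None:
    """Persist ``model`` as a single ``.pseg`` archive.

    The archive is a zip with a human-readable ``manifest.json`` plus the
    pickled classifier in ``classifier.bin``.
    """
    blob = pickle.dumps(model.classifier, protocol=4)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(model.manifest(), indent=2))
        zf.writestr("classifier.bin", blob)


def load_model(path) -> TrainedModel:
    """Load a ``.pseg`` archive written by :func:`save_model`."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for member in ("manifest.json", "classifier.bin"):
                if member not in names:
                    raise ModelFormatError(f"model archive is missing {member!r}")
            manifest = json.loads(zf.read("manifest.json"))
            blob = zf.read("classifier.bin")
    except zipfile.BadZipFile as exc:
        raise ModelFormatError(f"not a model archive: {exc}") from exc
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format_version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    classifier = pickle.loads(blob)
    return TrainedModel(
        classifier=classifier,
        extractor=ExtractorSpec.from_dict(manifest["extractor"]),
        normalization=NormalizationConfig.from_dict(manifest["normalization"]),
        classes=list(manifest["classes"]),
        n_channels=int(manifest["n_channels"]),
        seed=manifest.get("seed"),
        format_version=version,
        provenance=manifest.get("provenance", {}),
    )
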