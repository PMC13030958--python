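"""Feature extractors: pluggable producers of per-pixel feature maps.

An extractor is created from a declarative :class:`~scribseg.core.ExtractorSpec`
via :func:`create_extractor`.  All extractors consume ``(C, H, W)`` float
planes and emit ``(F, H, W)`` float maps, where ``F`` is a pure function of
the spec's parameters and the input channel count (exposed as
:meth:`FeatureExtractor.n_channels`).

Local extractors additionally declare a *context margin*: padding a crop by
at least this many pixels makes crop features bit-identical to full-image
features, which is what makes annotation-crop training and tiled prediction
exact.  Whole-image-context extractors (ViT-based) return ``None`` and refuse
tiling by default.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Sequence

import numpy as np

from ..core import ExtractorSpec, FeatureMap
from . import filters
from .backbones import (
    BackendMissingError,
    get_cnn_backend,
    get_vit_backend,
    register_cnn_backend,
    register_vit_backend,
)
from .pyramid import DEFAULT_LAYERS, DEFAULT_SCALES, extract_cnn_pyramid, pyramid_n_channels
from .vit import PatchGrid, extract_vit_patch, grid_side, upsample_patch_features

__all__ = [
    "FeatureExtractor",
    "create_extractor",
    "register_extractor",
    "make_spec",
    "context_margin",
    "combine_features",
    "extract_multiprojection",
    "extract_vit_patch",
    "upsample_patch_features",
    "PatchGrid",
    "BackendMissingError",
    "filters",
]


class FeatureExtractor:
    """Base class for all extractors; subclasses implement ``extract``."""

    def __init__(self, spec: ExtractorSpec) -> None:
        self.spec = spec

    # -- contract ---------------------------------------------------------
    def n_channels(self, n_input_channels: int) -> int:
        raise NotImplementedError

    def context_margin(self) -> "int | None":
        """Padding (pixels) for exact crop features; None if whole-image."""
        raise NotImplementedError

    @property
    def whole_image_context(self) -> bool:
        return self.context_margin() is None

    def extract(self, plane: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def extract_volume(self, volume: np.ndarray) -> np.ndarray:
        """Apply the extractor plane-wise along z of a (C, Z, Y, X) volume."""
        return np.stack(
            [self.extract(volume[:, z]) for z in range(volume.shape[1])], axis=1
        )

    def extract_map(self, plane: np.ndarray) -> FeatureMap:
        return FeatureMap(
            values=self.extract(plane), fingerprint=self.spec.fingerprint(), scale=1.0
        )


class GaussianBaselineExtractor(FeatureExtractor):
    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        self.sigma = float(spec.params.get("sigma", filters.DEFAULT_BASELINE_SIGMA))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def n_channels(self, n_input_channels: int) -> int:
        return filters.gaussian_baseline_n_channels(n_input_channels)

    def context_margin(self) -> int:
        return filters.gaussian_baseline_margin(self.sigma)

    def extract(self, plane: np.ndarray) -> np.ndarray:
        return filters.gaussian_baseline_channels(plane, self.sigma)


class FilterbankExtractor(FeatureExtractor):
    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        self.sigmas = tuple(
            float(s) for s in spec.params.get("sigmas", filters.DEFAULT_SIGMAS)
        )
        if not self.sigmas or any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be non-empty and strictly positive")

    def n_channels(self, n_input_channels: int) -> int:
        return filters.filterbank_n_channels(n_input_channels, len(self.sigmas))

    def context_margin(self) -> int:
        return filters.filterbank_margin(self.sigmas)

    def extract(self, plane: np.ndarray) -> np.ndarray:
        return filters.filterbank_channels(plane, self.sigmas)


class CNNPyramidExtractor(FeatureExtractor):
    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        p = spec.params
        self.backbone = get_cnn_backend(
            p.get("backbone", "tiny_vgg"), seed=int(p.get("backbone_seed", 0))
        )
        self.scales = tuple(int(s) for s in p.get("scales", DEFAULT_SCALES))
        self.layers = tuple(p.get("layers", DEFAULT_LAYERS))

    def n_channels(self, n_input_channels: int) -> int:
        # backbone widths are channel-count independent
        return pyramid_n_channels(self.backbone, self.layers, self.scales)

    def context_margin(self) -> int:
        # receptive field at the coarsest scale, plus resize support
        return self.backbone.receptive_field_radius() * max(self.scales) + max(self.scales)

    def extract(self, plane: np.ndarray) -> np.ndarray:
        return extract_cnn_pyramid(plane, self.backbone, self.scales, self.layers)


class ViTPatchExtractor(FeatureExtractor):
    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        p = spec.params
        self.backbone = get_vit_backend(
            p.get("backbone", "vit_small_p14"), seed=int(p.get("backbone_seed", 0))
        )
        self.patch_size = int(p.get("patch_size", self.backbone.patch_size))
        self.interpolation = p.get("interpolation", "nearest")

    def n_channels(self, n_input_channels: int) -> int:
        return int(self.backbone.embed_dim)

    def context_margin(self) -> None:
        return None  # global attention: whole-image context

    def extract_grid(self, plane: np.ndarray) -> PatchGrid:
        return extract_vit_patch(plane, self.backbone, self.patch_size)

    def extract(self, plane: np.ndarray) -> np.ndarray:
        grid = self.extract_grid(plane)
        return upsample_patch_features(grid, mode=self.interpolation)


class CombinedExtractor(FeatureExtractor):
    """Channel-wise concatenation of child extractors."""

    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        children = spec.params.get("children", [])
        if not children:
            raise ValueError("combined extractor needs at least one child spec")
        self.children = [create_extractor(ExtractorSpec.from_dict(c)) for c in children]

    def n_channels(self, n_input_channels: int) -> int:
        return sum(c.n_channels(n_input_channels) for c in self.children)

    def context_margin(self) -> "int | None":
        margins = [c.context_margin() for c in self.children]
        if any(m is None for m in margins):
            return None
        return max(margins)  # type: ignore[type-var]

    def extract(self, plane: np.ndarray) -> np.ndarray:
        return np.concatenate([c.extract(plane) for c in self.children], axis=0)


class MultiProjectionExtractor(FeatureExtractor):
    """Run a 2D base extractor along xy, xz and yz slices of a volume."""

    def __init__(self, spec: ExtractorSpec) -> None:
        super().__init__(spec)
        base = spec.params.get("base")
        if base is None:
            raise ValueError("multiprojection requires a 'base' child spec")
        self.base = create_extractor(ExtractorSpec.from_dict(base))
        if isinstance(self.base, MultiProjectionExtractor):
            raise ValueError("multiprojection cannot nest itself")

    def n_channels(self, n_input_channels: int) -> int:
        return 3 * self.base.n_channels(n_input_channels)

    def context_margin(self) -> "int | None":
        return self.base.context_margin()

    def extract(self, plane: np.ndarray) -> np.ndarray:
        raise ValueError(
            "multiprojection needs a 3D volume; use the base extractor "
            f"({self.base.spec.kind}) directly for 2D planes"
        )

    def extract_volume(self, volume: np.ndarray) -> np.ndarray:
        return extract_multiprojection(volume, self.base)


def extract_multiprojection(volume: np.ndarray, base: FeatureExtractor) -> np.ndarray:
    """Concatenate base features from xy, xz and yz slicings of a volume.

    ``volume`` is (C, Z, Y, X); the result is (3F, Z, Y, X) with the three
    orientation blocks in that order, each transposed back to (z, y, x).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 3:
        volume = volume[np.newaxis]
    if volume.ndim != 4:
        raise ValueError("expected a (C, Z, Y, X) volume")
    c, nz, ny, nx = volume.shape
    f = base.n_channels(c)

    xy = np.stack([base.extract(volume[:, z]) for z in range(nz)], axis=1)
    xz = np.empty((f, nz, ny, nx))
    for y in range(ny):
        xz[:, :, y, :] = base.extract(volume[:, :, y, :])
    yz = np.empty((f, nz, ny, nx))
    for x in range(nx):
        yz[:, :, :, x] = base.extract(volume[:, :, :, x])
    return np.concatenate([xy, xz, yz], axis=0)


def combine_features(maps: Sequence[FeatureMap]) -> FeatureMap:
    """Concatenate feature maps channel-wise, in list order."""
    if not maps:
        raise ValueError("need at least one feature map")
    shape = maps[0].spatial_shape
    for i, m in enumerate(maps):
        if m.scale != 1.0:
            raise ValueError(f"map {i} is not at scale 1 (scale={m.scale})")
        if m.spatial_shape != shape:
            raise ValueError(
                f"map {i} has spatial shape {m.spatial_shape}, expected {shape}"
            )
    if len(maps) == 1:
        return maps[0]
    import hashlib

    fp = hashlib.sha256("|".join(m.fingerprint for m in maps).encode()).hexdigest()[:16]
    return FeatureMap(
        values=np.concatenate([m.values for m in maps], axis=0),
        fingerprint=fp,
        scale=1.0,
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: Dict[str, Callable[[ExtractorSpec], FeatureExtractor]] = {
    "gaussian_baseline": GaussianBaselineExtractor,
    "filterbank": FilterbankExtractor,
    "cnn_pyramid": CNNPyramidExtractor,
    "vit_patch": ViTPatchExtractor,
    "combined": CombinedExtractor,
    "multiprojection": MultiProjectionExtractor,
}


def register_extractor(kind: str, factory: Callable[[ExtractorSpec], FeatureExtractor]) -> None:
    """Register a third-party extractor under a new kind name."""
    _REGISTRY[kind] = factory


def create_extractor(spec: ExtractorSpec) -> FeatureExtractor:
    try:
        factory = _REGISTRY[spec.kind]
    except KeyError:
        raise ValueError(
            f"unknown extractor kind {spec.kind!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(spec)


def make_spec(kind: str, **params) -> ExtractorSpec:
    """Build an ExtractorSpec with the whole-image-context flag derived from
    the realized extractor (single source of truth)."""
    spec = ExtractorSpec(kind=kind, params=params)
    ext = create_extractor(spec)
    return ExtractorSpec(
        kind=kind, params=params, whole_image_context=ext.whole_image_context
    )


def context_margin(spec: ExtractorSpec) -> "int | None":
    """Exact padding needed for crop features to equal full-image features;
    None for whole-image-context extractors."""
    return create_extractor(spec).context_margin()
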