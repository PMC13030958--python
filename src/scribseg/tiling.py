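"""Exact tiled prediction for large planes.

Core rectangles partition the plane; each is padded by a margin before
feature extraction.  With a margin of at least the extractor's context
margin, tiled output is bit-identical to untiled prediction, and the worker
count never affects results (tiles are independent, cores disjoint).
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .core import TrainedModel
from .features import create_extractor
from .train import _as_plane, _normalize_plane, predict_features

DEFAULT_TILE_SIZE = 512


@dataclass(frozen=True)
class Rect:
    y0: int
    y1: int
    x0: int
    x1: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y1 - self.y0, self.x1 - self.x0)


@dataclass(frozen=True)
class TilePlan:
    shape: tuple[int, int]
    tile_size: int
    margin: int
    tiles: tuple[tuple[Rect, Rect], ...]  # (core, padded)


def plan_tiles(shape: tuple[int, int], tile_size: int, margin: int) -> TilePlan:
    """Deterministic row-major tile plan; last row/column may be smaller.

    Padded rectangles extend cores by ``margin``, clipped to image bounds
    (reflective padding beyond the border is the extractor's own boundary
    handling)."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if tile_size < 2 * margin:
        warnings.warn(
            f"tile_size {tile_size} < 2x margin {margin}: padding dominates the work",
            stacklevel=2,
        )
    h, w = shape
    tiles = []
    for y0 in range(0, h, tile_size):
        for x0 in range(0, w, tile_size):
            core = Rect(y0, min(y0 + tile_size, h), x0, min(x0 + tile_size, w))
            padded = Rect(
                max(core.y0 - margin, 0),
                min(core.y1 + margin, h),
                max(core.x0 - margin, 0),
                min(core.x1 + margin, w),
            )
            tiles.append((core, padded))
    return TilePlan(shape=(h, w), tile_size=tile_size, margin=margin, tiles=tuple(tiles))


class GlobalContextTilingError(RuntimeError):
    pass


def predict_tiled(
    plane: np.ndarray,
    model: TrainedModel,
    plan: TilePlan | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    margin: int | None = None,
    workers: int = 1,
    allow_global_context: bool = False,
) -> np.ndarray:
    """Predict a plane tile by tile; exact when margin >= context margin.

    Whole-image-context extractors are refused unless
    ``allow_global_context=True`` (features would change across tiles).
    Normalization statistics are computed once on the full plane so tiling
    cannot alter them.
    """
    plane = _as_plane(plane)
    model.check_channels(plane.shape[0])
    ext = create_extractor(model.extractor)
    ext_margin = ext.context_margin()
    if ext_margin is None and not allow_global_context:
        raise GlobalContextTilingError(
            f"extractor {model.extractor.kind!r} requires whole-image context; "
            "tiling is disabled by default — pass allow_global_context=True "
            "(CLI: --allow-tiling-global-context) to force approximate tiling"
        )
    if plan is None:
        if margin is None:
            margin = ext_margin if ext_margin is not None else 0
        plan = plan_tiles(plane.shape[1:], tile_size, margin)
    plane_n = _normalize_plane(plane, model.normalization)
    out = np.zeros(plan.shape, dtype=np.int32)

    def work(item):
        core, padded = item
        crop = plane_n[:, padded.y0 : padded.y1, padded.x0 : padded.x1]
        labels, _ = predict_features(ext.extract(crop), model)
        oy, ox = core.y0 - padded.y0, core.x0 - padded.x0
        ch, cw = core.shape
        out[core.y0 : core.y1, core.x0 : core.x1] = labels[oy : oy + ch, ox : ox + cw]

    if workers <= 1:
        for item in plan.tiles:
            work(item)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(work, plan.tiles))
    return out
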