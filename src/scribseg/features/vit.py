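"""Patch-feature extraction via a ViT-style backbone, and back-mapping of
patch grids to full-resolution feature maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize


@dataclass(frozen=True)
class PatchGrid:
    """Per-patch embeddings plus the geometry needed for exact back-mapping.

    ``origin_offset`` records, per side, how many pixels the resize added
    (positive) or removed (negative) relative to the original image.
    """

    embeddings: np.ndarray  # (grid_y, grid_x, D)
    patch_size: int
    origin_offset: tuple[int, int]
    original_shape: tuple[int, int]
    resized_shape: tuple[int, int]

    @property
    def embed_dim(self) -> int:
        return self.embeddings.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.embeddings.shape[:2]


def grid_side(side: int, patch_size: int) -> int:
    """Resized side length: the nearest positive multiple of patch_size."""
    return max(int(round(side / patch_size)), 1) * patch_size


def extract_vit_patch(plane: np.ndarray, backbone, patch_size: int) -> PatchGrid:
    """Resize a (C, H, W) plane to the nearest patch-multiple per side
    (bilinear) and embed its non-overlapping patches."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim == 2:
        plane = plane[np.newaxis]
    _, h, w = plane.shape
    rh, rw = grid_side(h, patch_size), grid_side(w, patch_size)
    if (rh, rw) != (h, w):
        resized = np.stack(
            [
                resize(ch, (rh, rw), order=1, mode="reflect", preserve_range=True,
                       anti_aliasing=False)
                for ch in plane
            ]
        )
    else:
        resized = plane
    emb = backbone.embed_patches(resized)
    return PatchGrid(
        embeddings=np.asarray(emb),
        patch_size=patch_size,
        origin_offset=(rh - h, rw - w),
        original_shape=(h, w),
        resized_shape=(rh, rw),
    )


def upsample_patch_features(
    grid: PatchGrid,
    target_shape: tuple[int, int] | None = None,
    mode: str = "nearest",
) -> np.ndarray:
    """Expand a PatchGrid to a (D, H, W) map at the original resolution.

    ``nearest`` (default) assigns each pixel the embedding of its covering
    patch — embeddings are copied, never mixed.  ``bilinear`` interpolates
    between patch centers.
    """
    if target_shape is None:
        target_shape = grid.original_shape
    if tuple(target_shape) != grid.original_shape:
        raise ValueError(
            f"target_shape {tuple(target_shape)} != original shape "
            f"{grid.original_shape} recorded in the grid"
        )
    h, w = target_shape
    rh, rw = grid.resized_shape
    ps = grid.patch_size
    gy, gx = grid.grid_shape
    emb = grid.embeddings

    # pixel centers mapped into resized coordinates
    ys = (np.arange(h) + 0.5) * (rh / h) - 0.5
    xs = (np.arange(w) + 0.5) * (rw / w) - 0.5
    if mode == "nearest":
        py = np.clip(np.round(ys).astype(int) // ps, 0, gy - 1)
        px = np.clip(np.round(xs).astype(int) // ps, 0, gx - 1)
        out = emb[py[:, None], px[None, :], :]  # (H, W, D)
        return np.ascontiguousarray(out.transpose(2, 0, 1))
    if mode == "bilinear":
        # patch-center coordinates in patch-grid units
        cy = (ys - (ps - 1) / 2.0) / ps
        cx = (xs - (ps - 1) / 2.0) / ps
        coords = np.meshgrid(np.clip(cy, 0, gy - 1), np.clip(cx, 0, gx - 1),
                             indexing="ij")
        out = np.empty((emb.shape[2], h, w))
        for d in range(emb.shape[2]):
            out[d] = ndi.map_coordinates(emb[:, :, d], coords, order=1,
                                         mode="nearest")
        return out
    raise ValueError(f"unknown interpolation mode {mode!r}")
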