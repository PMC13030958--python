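"""Featurized image pyramid over a convolutional backbone.

Downscaled copies of the input are passed through the backbone; selected layer
outputs are upscaled back to the input resolution and concatenated across
layers and scales, mixing receptive-field sizes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import resize

ALLOWED_SCALES = (1, 2, 4, 8)

DEFAULT_SCALES = (1, 2)
DEFAULT_LAYERS = ("s1", "s2", "s3")


def _resize_plane(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if plane.shape[1:] == shape:
        return plane
    return np.stack(
        [
            resize(ch, shape, order=1, mode="reflect", preserve_range=True,
                   anti_aliasing=False)
            for ch in plane
        ]
    )


def pyramid_n_channels(backbone, layers: Sequence[str], scales: Sequence[int]) -> int:
    widths = {info.name: info.channels for info in backbone.layers()}
    return sum(widths[name] for name in layers) * len(scales)


def extract_cnn_pyramid(
    plane: np.ndarray,
    backbone,
    scales: Sequence[int] = DEFAULT_SCALES,
    layers: Sequence[str] = DEFAULT_LAYERS,
) -> np.ndarray:
    """Return a (F, H, W) map; F = sum of selected layer widths x len(scales)."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim == 2:
        plane = plane[np.newaxis]
    scales = tuple(int(s) for s in scales)
    if not scales or any(s not in ALLOWED_SCALES for s in scales):
        raise ValueError(f"scales must be a non-empty subset of {ALLOWED_SCALES}")
    known = {info.name for info in backbone.layers()}
    missing = [l for l in layers if l not in known]
    if missing:
        raise ValueError(f"backbone has no layers {missing}; available {sorted(known)}")
    h, w = plane.shape[1:]
    min_side = getattr(backbone, "min_input_side", 1)
    for s in scales:
        if min(h // s, w // s) < min_side:
            raise ValueError(
                f"image {h}x{w} is smaller than the backbone minimum "
                f"({min_side}) after downscaling by {s}"
            )
    blocks: list[np.ndarray] = []
    for s in scales:
        scaled = _resize_plane(plane, (h // s, w // s)) if s > 1 else plane
        outputs = backbone.forward(scaled)
        for name in layers:
            feat = outputs[name]
            blocks.append(
                np.stack(
                    [
                        feat[i] if feat.shape[1:] == (h, w)
                        else resize(feat[i], (h, w), order=1, mode="reflect",
                                    preserve_range=True, anti_aliasing=False)
                        for i in range(feat.shape[0])
                    ]
                )
            )
    return np.concatenate(blocks, axis=0)
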