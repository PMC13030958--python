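"""Randomly initialized backbone providers for the CNN-pyramid and ViT
extractors.

Pretrained networks are deliberately not shipped: backbones are pluggable
providers satisfying two small contracts, and the built-in ones are tiny
seeded numpy architectures matching the declared geometry of their pretrained
counterparts (patch size 14 with 384-wide embeddings for the small ViT,
patch size 16 with 1024-wide embeddings for the large histology-style ViT).
Third-party backends register themselves under a new name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
from scipy import ndimage as ndi


class BackendMissingError(RuntimeError):
    """Raised when a named backbone backend is not registered."""


# ---------------------------------------------------------------------------
# CNN backbone
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNLayerInfo:
    name: str
    channels: int
    downsample: int


class TinyConvBackbone:
    """A small VGG-style stack of seeded random 3x3 convolutions.

    Exposes named layers with declared channel counts and downsampling
    factors, as required by the pyramid extractor's provider contract.
    Convolutions use reflective padding; downsampling is 2x2 max pooling.
    """

    def __init__(
        self,
        stage_widths: tuple[int, ...] = (16, 32, 64),
        convs_per_stage: tuple[int, ...] = (2, 2, 1),
        seed: int = 0,
    ) -> None:
        if len(stage_widths) != len(convs_per_stage):
            raise ValueError("stage_widths and convs_per_stage length mismatch")
        self.stage_widths = stage_widths
        self.convs_per_stage = convs_per_stage
        self.seed = seed
        self._weights: dict[tuple[int, int, int], np.ndarray] = {}

    # -- provider contract ------------------------------------------------
    def layers(self) -> list[CNNLayerInfo]:
        return [
            CNNLayerInfo(f"s{i + 1}", w, 2**i)
            for i, w in enumerate(self.stage_widths)
        ]

    @property
    def min_input_side(self) -> int:
        return 2 ** (len(self.stage_widths) - 1)

    def receptive_field_radius(self) -> int:
        r = 0
        for i, n_convs in enumerate(self.convs_per_stage):
            ds = 2**i
            r += n_convs * ds  # each 3x3 conv adds one pixel at its scale
            if i > 0:
                r += ds  # pooling window slack
        return r

    def _weight(self, stage: int, conv: int, in_ch: int) -> np.ndarray:
        key = (stage, conv, in_ch)
        if key not in self._weights:
            out_ch = self.stage_widths[stage]
            rng = np.random.default_rng(
                (self.seed, stage, conv, in_ch, out_ch)
            )
            fan_in = in_ch * 9
            self._weights[key] = rng.normal(
                0.0, math.sqrt(2.0 / fan_in), size=(out_ch, in_ch, 3, 3)
            )
        return self._weights[key]

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        out = np.empty((w.shape[0],) + x.shape[1:], dtype=np.float64)
        for oc in range(w.shape[0]):
            acc = np.zeros(x.shape[1:], dtype=np.float64)
            for ic in range(x.shape[0]):
                acc += ndi.correlate(x[ic], w[oc, ic], mode="reflect")
            out[oc] = acc
        return out

    def forward(self, plane: np.ndarray) -> dict[str, np.ndarray]:
        """Run the stack on a (C, H, W) plane; return {layer name: (F, h, w)}."""
        x = np.asarray(plane, dtype=np.float64)
        if x.ndim != 3:
            raise ValueError("expected a (C, H, W) plane")
        outputs: dict[str, np.ndarray] = {}
        for i in range(len(self.stage_widths)):
            if i > 0:
                h, w = x.shape[1:]
                x = x[:, : h - h % 2, : w - w % 2]
                x = x.reshape(x.shape[0], x.shape[1] // 2, 2, x.shape[2] // 2, 2)
                x = x.mean(axis=(2, 4))
            for j in range(self.convs_per_stage[i]):
                x = np.maximum(self._conv(x, self._weight(i, j, x.shape[0])), 0.0)
            outputs[f"s{i + 1}"] = x
        return outputs


# ---------------------------------------------------------------------------
# ViT backbone
# ---------------------------------------------------------------------------


def _sinusoidal_positions(gy: int, gx: int, dim: int) -> np.ndarray:
    pos = np.zeros((gy, gx, dim))
    half = dim // 2
    div = np.exp(-np.log(10000.0) * np.arange(half // 2) / max(half // 2, 1))
    ys = np.arange(gy)[:, None] * div[None, :]
    xs = np.arange(gx)[:, None] * div[None, :]
    pos[:, :, 0 : half // 2] = np.sin(ys)[:, None, :]
    pos[:, :, half // 2 : half] = np.cos(ys)[:, None, :]
    pos[:, :, half : half + half // 2] = np.sin(xs)[None, :, :]
    pos[:, :, half + half // 2 : 2 * (half // 2) + half] = np.cos(xs)[None, :, :]
    return pos


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _layer_norm(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return (x - mu) / (sd + 1e-6)


class TinyViTBackbone:
    """A minimal seeded vision transformer over non-overlapping patches.

    Global softmax attention makes every patch feature depend on the whole
    image, which is exactly why tiling is refused for this extractor family.
    """

    def __init__(
        self,
        patch_size: int,
        embed_dim: int,
        depth: int = 2,
        n_heads: int = 6,
        mlp_ratio: int = 2,
        seed: int = 0,
    ) -> None:
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.depth = depth
        self.n_heads = n_heads
        self.mlp_ratio = mlp_ratio
        self.seed = seed
        self._params: dict = {}

    def _rng(self, *key) -> np.random.Generator:
        import hashlib

        digest = hashlib.sha256(repr((self.embed_dim, key)).encode()).digest()
        return np.random.default_rng((self.seed, int.from_bytes(digest[:8], "big")))

    def _embed_weight(self, in_ch: int) -> np.ndarray:
        key = ("embed", in_ch)
        if key not in self._params:
            n_in = in_ch * self.patch_size**2
            self._params[key] = self._rng(*key).normal(
                0.0, 1.0 / math.sqrt(n_in), size=(n_in, self.embed_dim)
            )
        return self._params[key]

    def _block_params(self, i: int) -> dict:
        if ("block", i) not in self._params:
            d, r = self.embed_dim, self.mlp_ratio
            rng = self._rng("block", i)
            s = 1.0 / math.sqrt(d)
            self._params[("block", i)] = {
                "wq": rng.normal(0, s, (d, d)),
                "wk": rng.normal(0, s, (d, d)),
                "wv": rng.normal(0, s, (d, d)),
                "wo": rng.normal(0, s, (d, d)),
                "w1": rng.normal(0, s, (d, r * d)),
                "w2": rng.normal(0, 1.0 / math.sqrt(r * d), (r * d, d)),
            }
        return self._params[("block", i)]

    def _attention(self, x: np.ndarray, p: dict) -> np.ndarray:
        n, d = x.shape
        h = self.n_heads
        hd = d // h
        q = (x @ p["wq"]).reshape(n, h, hd).transpose(1, 0, 2)
        k = (x @ p["wk"]).reshape(n, h, hd).transpose(1, 0, 2)
        v = (x @ p["wv"]).reshape(n, h, hd).transpose(1, 0, 2)
        att = _softmax(q @ k.transpose(0, 2, 1) / math.sqrt(hd))
        out = (att @ v).transpose(1, 0, 2).reshape(n, d)
        return out @ p["wo"]

    def embed_patches(self, plane: np.ndarray) -> np.ndarray:
        """Embed a (C, H, W) plane whose sides are multiples of patch_size.

        Returns a (grid_y, grid_x, embed_dim) array of patch features.
        """
        x = np.asarray(plane, dtype=np.float64)
        c, h, w = x.shape
        ps = self.patch_size
        if h % ps or w % ps:
            raise ValueError("plane sides must be multiples of patch_size")
        gy, gx = h // ps, w // ps
        patches = (
            x.reshape(c, gy, ps, gx, ps)
            .transpose(1, 3, 0, 2, 4)
            .reshape(gy * gx, c * ps * ps)
        )
        tokens = patches @ self._embed_weight(c)
        tokens = tokens + _sinusoidal_positions(gy, gx, self.embed_dim).reshape(
            gy * gx, self.embed_dim
        )
        for i in range(self.depth):
            p = self._block_params(i)
            tokens = tokens + self._attention(_layer_norm(tokens), p)
            hid = np.maximum(_layer_norm(tokens) @ p["w1"], 0.0)
            tokens = tokens + hid @ p["w2"]
        return tokens.reshape(gy, gx, self.embed_dim)


# ---------------------------------------------------------------------------
# Backend registries
# ---------------------------------------------------------------------------

_CNN_BACKENDS: Dict[str, Callable[[int], TinyConvBackbone]] = {}
_VIT_BACKENDS: Dict[str, Callable[[int], TinyViTBackbone]] = {}


def register_cnn_backend(name: str, factory: Callable[[int], object]) -> None:
    _CNN_BACKENDS[name] = factory


def register_vit_backend(name: str, factory: Callable[[int], object]) -> None:
    _VIT_BACKENDS[name] = factory


def get_cnn_backend(name: str, seed: int = 0):
    try:
        factory = _CNN_BACKENDS[name]
    except KeyError:
        raise BackendMissingError(
            f"CNN backend {name!r} is not registered; available: "
            f"{sorted(_CNN_BACKENDS)}. Register a provider with "
            "scribseg.features.backbones.register_cnn_backend()."
        ) from None
    return factory(seed)


def get_vit_backend(name: str, seed: int = 0):
    try:
        factory = _VIT_BACKENDS[name]
    except KeyError:
        raise BackendMissingError(
            f"ViT backend {name!r} is not registered; available: "
            f"{sorted(_VIT_BACKENDS)}. Register a provider with "
            "scribseg.features.backbones.register_vit_backend()."
        ) from None
    return factory(seed)


register_cnn_backend("tiny_vgg", lambda seed: TinyConvBackbone(seed=seed))
register_cnn_backend(
    "tiny_vgg_wide",
    lambda seed: TinyConvBackbone(stage_widths=(64, 128), convs_per_stage=(2, 2), seed=seed),
)
# Geometry of the small general-purpose ViT: 14 px patches, 384-d embeddings.
register_vit_backend(
    "vit_small_p14", lambda seed: TinyViTBackbone(14, 384, n_heads=6, seed=seed)
)
# Geometry of the large histology-style ViT: 16 px patches, 1024-d embeddings.
register_vit_backend(
    "vit_large_p16", lambda seed: TinyViTBackbone(16, 1024, n_heads=16, seed=seed)
)
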