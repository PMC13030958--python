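"""Seeded synthetic fixtures for tests and benchmarks.

These generators stand in for external datasets: every fixture pairs an
intensity image (or stack) with a dense ground-truth label mask, and each
kind is solvable by the extractor family it is designed to exercise:

* ``intensity_separable`` — classes differ in mean intensity.
* ``texture_separable`` — equal means, different spatial autocorrelation.
* ``semantic_context`` — locally identical textures whose class is encoded
  only by large-scale surroundings (a bright/dark ring far from the object),
  so local filters fail while large-context features succeed.
* ``instances`` — blob instance labels, input for instance-to-semantic
  conversion.
* ``volume3d`` — ellipsoids in noise across z.
* ``multichannel`` — class information carried by the joint channel
  statistics; each single channel's marginal is identical across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .bench import ScribbleConfig, generate_scribbles
from .core import AnnotationMask, ImageStack

FIXTURE_KINDS = (
    "intensity_separable",
    "texture_separable",
    "semantic_context",
    "instances",
    "volume3d",
    "multichannel",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    shape: tuple[int, ...] = (128, 128)
    n_classes: int = 2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _region_labels(shape, n_classes, rng, smooth=8.0) -> np.ndarray:
    """Organic multi-class regions: quantile-thresholded smooth random field."""
    f = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    qs = np.quantile(f, np.linspace(0, 1, n_classes + 1)[1:-1])
    return (np.digitize(f, qs) + 1).astype(np.int32)


def _texture(shape, scale, rng) -> np.ndarray:
    """Zero-mean unit-variance texture with autocorrelation length ~ scale."""
    t = ndi.gaussian_filter(rng.normal(size=shape), scale)
    sd = t.std()
    return t / sd if sd > 0 else t


def make_fixture(spec: FixtureSpec) -> tuple[ImageStack, np.ndarray]:
    """Generate ``(ImageStack, ground-truth label mask)`` for a FixtureSpec."""
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind
    if kind == "intensity_separable":
        gt = _region_labels(spec.shape, spec.n_classes, rng)
        sep = max(4.0 * spec.noise_sd, 0.15)
        means = 0.2 + sep * np.arange(spec.n_classes)
        img = means[gt - 1] + rng.normal(0, spec.noise_sd, spec.shape)
        return ImageStack(img, ("y", "x")), gt

    if kind == "texture_separable":
        # large coherent regions (smoothness tied to image size) keep the
        # boundary-length penalty on per-pixel texture classification low
        gt = _region_labels(spec.shape, spec.n_classes, rng,
                            smooth=min(spec.shape) / 8.0)
        scales = 0.75 * (4.0 ** np.arange(spec.n_classes))
        img = np.zeros(spec.shape)
        for c in range(1, spec.n_classes + 1):
            tex = 0.5 + 0.3 * _texture(spec.shape, scales[c - 1], rng)
            img[gt == c] = tex[gt == c]
        img += rng.normal(0, spec.noise_sd, spec.shape)
        return ImageStack(img, ("y", "x")), gt

    if kind == "semantic_context":
        return _make_semantic_context(spec, rng)

    if kind == "instances":
        h, w = spec.shape
        gt = np.zeros((h, w), dtype=np.int32)
        n_blobs = max((h * w) // 600, 4)
        rr = rng
        idx = 1
        for _ in range(n_blobs):
            cy, cx = rr.integers(5, h - 5), rr.integers(5, w - 5)
            r = int(rr.integers(3, 7))
            yy, xx = np.ogrid[:h, :w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if not np.any(gt[blob]):
                gt[blob] = idx
                idx += 1
        img = np.where(gt > 0, 0.8, 0.2) + rng.normal(0, spec.noise_sd, (h, w))
        return ImageStack(img, ("y", "x")), gt

    if kind == "volume3d":
        if len(spec.shape) != 3:
            raise ValueError("volume3d needs a (z, y, x) shape")
        nz, ny, nx = spec.shape
        gt = np.zeros(spec.shape, dtype=np.int32)
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        n_ell = max(nz * ny * nx // 4000, 2)
        for _ in range(n_ell):
            cz, cy, cx = (rng.integers(2, s - 2) for s in spec.shape)
            rz, ry, rx = rng.integers(2, 4), rng.integers(3, 6), rng.integers(3, 6)
            ell = (
                ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
            ) <= 1.0
            gt[ell] = 1
        gt[gt == 0] = 2
        img = np.where(gt == 1, 0.8, 0.2) + rng.normal(0, spec.noise_sd, spec.shape)
        return ImageStack(img, ("plane", "y", "x")), gt

    if kind == "multichannel":
        # block mosaic; each block gets a class and a channel pattern whose
        # single-channel marginals match across classes: class 1 is
        # (lo, lo) | (hi, hi), class 2 is (lo, hi) | (hi, lo) — only the
        # joint channel statistics are informative
        h, w = spec.shape
        block = 12
        gt = np.zeros((h, w), dtype=np.int32)
        img = np.zeros((2, h, w))
        patterns = {1: [(0.3, 0.3), (0.7, 0.7)], 2: [(0.3, 0.7), (0.7, 0.3)]}
        for by in range(0, h, block):
            for bx in range(0, w, block):
                cls = int(rng.integers(1, 3))
                p = patterns[cls][int(rng.integers(2))]
                sl = (slice(by, by + block), slice(bx, bx + block))
                gt[sl] = cls
                img[0][sl] = p[0]
                img[1][sl] = p[1]
        img += rng.normal(0, spec.noise_sd, img.shape)
        return ImageStack(img, ("channel", "y", "x")), gt

    raise AssertionError("unreachable")


def _make_semantic_context(spec: FixtureSpec, rng: np.random.Generator):
    """Disks with identical texture; class encoded by a distant ring."""
    cell = 56
    disk_r, ring_in, ring_out = 5, 18, 26
    if len(spec.shape) != 2:
        raise ValueError("semantic_context needs a 2D shape")
    h = (spec.shape[0] // cell) * cell
    w = (spec.shape[1] // cell) * cell
    if h < cell or w < cell:
        raise ValueError(f"semantic_context needs sides >= {cell}")
    gt = np.full((h, w), 3, dtype=np.int32)  # class 3 = background
    img = np.full((h, w), 0.5)
    yy, xx = np.ogrid[:cell, :cell]
    cy = cx = cell // 2
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disk_m = d2 <= disk_r**2
    ring_m = (d2 >= ring_in**2) & (d2 <= ring_out**2)
    for by in range(0, h, cell):
        for bx in range(0, w, cell):
            cls = int(rng.integers(1, 3))  # 1 or 2
            sl = (slice(by, by + cell), slice(bx, bx + cell))
            img[sl][disk_m] = 0.8  # identical appearance for both classes
            img[sl][ring_m] = 0.9 if cls == 1 else 0.1
            gt[sl][disk_m] = cls
    img += rng.normal(0, max(spec.noise_sd, 0.02), (h, w))
    return ImageStack(img, ("y", "x")), gt


def make_annotation_subset(gt: np.ndarray, cfg: ScribbleConfig) -> AnnotationMask:
    """Thin wrapper over the benchmark scribble generator so fixtures and
    benchmarks share one scribble path."""
    if cfg.density == 0:
        import warnings

        warnings.warn("density 0 requested: returning an empty annotation mask")
        return AnnotationMask(labels=np.zeros(np.asarray(gt).shape, dtype=np.int32))
    return generate_scribbles(gt, cfg)


def autocorrelation_length(values: np.ndarray, mask: np.ndarray, max_lag: int = 20) -> float:
    """Horizontal autocorrelation e-folding length estimated on masked pixels."""
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    sel = values[mask]
    mu, sd = sel.mean(), sel.std()
    acf = [1.0]
    for lag in range(1, max_lag + 1):
        a = values[:, :-lag]
        b = values[:, lag:]
        m = mask[:, :-lag] & mask[:, lag:]
        if m.sum() < 10:
            break
        acf.append(float(((a[m] - mu) * (b[m] - mu)).mean() / (sd**2)))
    acf_arr = np.asarray(acf)
    thresh = 1.0 / np.e
    below = np.nonzero(acf_arr < thresh)[0]
    if below.size == 0:
        return float(len(acf_arr))
    i = below[0]
    # linear interpolation between lag i-1 and i
    a0, a1 = acf_arr[i - 1], acf_arr[i]
    return float(i - 1 + (a0 - thresh) / (a0 - a1))
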