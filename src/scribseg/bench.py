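"""Scribble synthesis from ground-truth masks, dataset preparation, and
mIoU scoring.

Human-like scribbles are composed from three line families per class:

1. center ridge lines, sampled from the primary (medial) skeleton of the
   class mask;
2. boundary-parallel lines, sampled from the secondary skeleton — the
   skeleton of the mask after subtracting the (dilated) primary skeleton;
3. boundary-perpendicular lines, connecting the primary skeleton to the
   mask boundary.

Strokes are cut to a length range, dilated to a stroke width, and accumulated
until the requested fraction of image pixels is annotated (the last stroke is
trimmed to land on the target).  Every annotated pixel keeps the ground-truth
label at that position, so generated scribbles are pure by construction.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, skeletonize

from .core import AnnotationMask, ExtractorSpec, ImageStack, NormalizationConfig

#: Annotation levels used throughout the benchmark (fractions of all pixels).
BENCHMARK_DENSITIES = (0.0025, 0.01, 0.025)

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class ScribbleConfig:
    """Parameters of the scribble generator."""

    density: float = 0.01
    width: int = 1
    length_range: tuple[int, int] = (10, 30)
    mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # ridge, parallel, perpendicular
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.density < 1:
            raise ValueError("density must be in [0, 1)")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")
        if abs(sum(self.mix) - 1.0) > 1e-9 or any(m < 0 for m in self.mix):
            raise ValueError("mix must be non-negative and sum to 1")


#: Stroke-style presets: many short 1-px scribbles for cell-like images,
#: fewer long 2-px strokes for natural images, medium 2-px for histology.
PRESETS: Mapping[str, ScribbleConfig] = {
    "cell": ScribbleConfig(width=1, length_range=(5, 15)),
    "natural": ScribbleConfig(width=2, length_range=(30, 80)),
    "histology": ScribbleConfig(width=2, length_range=(15, 40)),
}


def preset_config(name: str, density: float, seed: int = 0) -> ScribbleConfig:
    base = PRESETS[name]
    return replace(base, density=density, seed=seed)


# ---------------------------------------------------------------------------
# Skeletons and line generators
# ---------------------------------------------------------------------------


def primary_skeleton(class_mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide medial skeleton, fully inside the mask."""
    mask = np.asarray(class_mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask)


def secondary_skeleton(
    class_mask: np.ndarray, primary: np.ndarray, width: int = 1
) -> np.ndarray:
    """Skeleton of the mask minus the primary skeleton dilated by ``width``."""
    mask = np.asarray(class_mask, dtype=bool)
    primary = np.asarray(primary, dtype=bool)
    if np.any(primary & ~mask):
        raise ValueError("primary skeleton must lie inside the mask")
    remainder = mask & ~dilation(primary, disk(width))
    if not remainder.any():
        return np.zeros_like(mask)
    return skeletonize(remainder)


def _walk_skeleton(
    skel: np.ndarray, start: tuple[int, int], length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random non-revisiting walk along skeleton pixels, up to ``length``."""
    h, w = skel.shape
    path = [start]
    visited = {start}
    cur = start
    while len(path) < length:
        options = []
        for dy, dx in _NEIGHBORS8:
            ny, nx = cur[0] + dy, cur[1] + dx
            if 0 <= ny < h and 0 <= nx < w and skel[ny, nx] and (ny, nx) not in visited:
                options.append((ny, nx))
        if not options:
            break
        cur = options[rng.integers(len(options))]
        path.append(cur)
        visited.add(cur)
    return path


def _descend_to_boundary(
    edt: np.ndarray,
    mask: np.ndarray,
    start: tuple[int, int],
    max_len: int,
    rng: "np.random.Generator | None" = None,
) -> list[tuple[int, int]]:
    """Descend the distance transform from ``start`` to the mask boundary;
    the path stays strictly inside the mask.  When an rng is given, one of
    the descending neighbors is picked at random (diversifies the line set);
    otherwise the steepest descent is taken."""
    h, w = mask.shape
    path = [start]
    cur = start
    visited = {start}
    while edt[cur] > 1 and len(path) < max_len:
        options = []
        for dy, dx in _NEIGHBORS8:
            ny, nx = cur[0] + dy, cur[1] + dx
            if (
                0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                and (ny, nx) not in visited and edt[ny, nx] < edt[cur]
            ):
                options.append((ny, nx))
        if not options:
            break
        if rng is None:
            cur = min(options, key=lambda p: edt[p])
        else:
            cur = options[rng.integers(len(options))]
        path.append(cur)
        visited.add(cur)
    return path


def perpendicular_lines(
    class_mask: np.ndarray,
    primary: np.ndarray,
    rng: np.random.Generator,
    n_lines: int = 1,
    max_len: int = 10_000,
) -> list[list[tuple[int, int]]]:
    """Lines from sampled primary-skeleton pixels to the nearest boundary."""
    mask = np.asarray(class_mask, dtype=bool)
    pys, pxs = np.nonzero(primary)
    if pys.size == 0:
        return []
    edt = ndi.distance_transform_edt(mask)
    lines = []
    for _ in range(n_lines):
        i = rng.integers(pys.size)
        lines.append(_descend_to_boundary(edt, mask, (int(pys[i]), int(pxs[i])), max_len))
    return lines


def _random_straight_path(
    mask: np.ndarray,
    start: tuple[int, int],
    length: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Straight stroke in a random direction, clipped to the mask.

    Used as a fallback when the skeleton-derived generators run out of fresh
    pixels before the requested density is reached (e.g. one class covering
    the whole image)."""
    h, w = mask.shape
    theta = rng.uniform(0, 2 * np.pi)
    dy, dx = np.sin(theta), np.cos(theta)
    path = []
    seen = set()
    for t in range(length * 2):  # oversample the parametric line
        y = int(round(start[0] + dy * t / 2))
        x = int(round(start[1] + dx * t / 2))
        if not (0 <= y < h and 0 <= x < w) or not mask[y, x]:
            break
        if (y, x) not in seen:
            seen.add((y, x))
            path.append((y, x))
        if len(path) >= length:
            break
    return path


def _width_offsets(width: int) -> list[tuple[int, int]]:
    lo = -(width // 2)
    rng_ = range(lo, lo + width)
    return [(dy, dx) for dy in rng_ for dx in rng_]


def _dilate_path(
    path: Sequence[tuple[int, int]],
    mask: np.ndarray,
    width: int,
) -> list[tuple[int, int]]:
    """Thicken a pixel path to ``width``, clipped to the class mask, keeping
    path order (so trimming cuts the stroke's tail, not random pixels)."""
    h, w = mask.shape
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    offsets = _width_offsets(width)
    for y, x in path:
        for dy, dx in offsets:
            p = (y + dy, x + dx)
            if p not in seen and 0 <= p[0] < h and 0 <= p[1] < w and mask[p]:
                seen.add(p)
                out.append(p)
    return out


# ---------------------------------------------------------------------------
# Scribble generation
# ---------------------------------------------------------------------------


@dataclass
class _ClassState:
    mask: np.ndarray
    primary_pixels: np.ndarray
    primary: np.ndarray
    secondary_pixels: np.ndarray
    secondary: np.ndarray
    edt: np.ndarray


def _class_state(mask: np.ndarray, width: int) -> _ClassState:
    primary = primary_skeleton(mask)
    secondary = secondary_skeleton(mask, primary, width)
    return _ClassState(
        mask=mask,
        primary=primary,
        primary_pixels=np.column_stack(np.nonzero(primary)),
        secondary=secondary,
        secondary_pixels=np.column_stack(np.nonzero(secondary)),
        edt=ndi.distance_transform_edt(mask),
    )


def generate_scribbles(gt: np.ndarray, cfg: ScribbleConfig) -> AnnotationMask:
    """Synthesize a scribble annotation mask from a ground-truth label mask.

    The per-class stroke budget is proportional to class area; strokes are
    drawn from the three line generators according to ``cfg.mix``, cut to
    ``cfg.length_range``, dilated to ``cfg.width`` and clipped to their class
    region.  Accumulation stops once the total annotated fraction reaches
    ``cfg.density`` (the last stroke is trimmed).  If a class cannot host
    enough strokes the achieved density falls short and a warning is issued.
    """
    gt = np.asarray(gt)
    if gt.ndim != 2:
        raise ValueError("ground truth must be a 2D label mask")
    classes = [int(c) for c in np.unique(gt) if c != 0]
    if not classes:
        raise ValueError("ground truth contains no annotatable classes (all zero)")
    rng = np.random.default_rng(cfg.seed)
    out = np.zeros(gt.shape, dtype=np.int32)
    total_target = int(round(cfg.density * gt.size))
    areas = {c: int((gt == c).sum()) for c in classes}
    total_area = sum(areas.values())

    lmin, lmax = cfg.length_range
    for c in classes:
        budget = int(round(total_target * areas[c] / total_area))
        if budget == 0:
            continue
        state = _class_state(gt == c, cfg.width)
        if state.primary_pixels.size == 0:
            warnings.warn(f"class {c}: region too small to skeletonize; skipped")
            continue
        count = 0
        failures = 0
        while count < budget and failures < 300:
            kind = rng.choice(3, p=cfg.mix)
            length = int(rng.integers(lmin, lmax + 1))
            if kind == 0 or (kind == 1 and state.secondary_pixels.size == 0):
                pix = state.primary_pixels
                i = rng.integers(len(pix))
                path = _walk_skeleton(state.primary, tuple(pix[i]), length, rng)
            elif kind == 1:
                pix = state.secondary_pixels
                i = rng.integers(len(pix))
                path = _walk_skeleton(state.secondary, tuple(pix[i]), length, rng)
            else:
                pix = state.primary_pixels
                i = rng.integers(len(pix))
                path = _descend_to_boundary(
                    state.edt, state.mask, tuple(pix[i]), lmax, rng=rng
                )
            stroke = _dilate_path(path, state.mask, cfg.width)
            fresh = [p for p in stroke if out[p] == 0]
            if len(fresh) == 0:
                failures += 1
                continue
            failures = 0
            if count + len(fresh) > budget:
                fresh = fresh[: budget - count]
            for p in fresh:
                out[p] = c
            count += len(fresh)
        if count < budget:
            # skeleton material exhausted: top up with random straight strokes
            count = _top_up_class(out, state.mask, c, budget, count,
                                  cfg, rng)
        if count < budget:
            warnings.warn(
                f"class {c}: requested {budget} annotated pixels, achieved {count}"
            )
    return AnnotationMask(labels=out)


def _top_up_class(
    out: np.ndarray,
    mask: np.ndarray,
    c: int,
    budget: int,
    count: int,
    cfg: ScribbleConfig,
    rng: np.random.Generator,
) -> int:
    lmin, lmax = cfg.length_range
    failures = 0
    while count < budget and failures < 200:
        free_ys, free_xs = np.nonzero(mask & (out == 0))
        if free_ys.size == 0:
            break
        i = rng.integers(free_ys.size)
        length = int(rng.integers(lmin, lmax + 1))
        path = _random_straight_path(
            mask, (int(free_ys[i]), int(free_xs[i])), length, rng
        )
        stroke = _dilate_path(path, mask, cfg.width)
        fresh = [p for p in stroke if out[p] == 0]
        if not fresh:
            failures += 1
            continue
        failures = 0
        if count + len(fresh) > budget:
            fresh = fresh[: budget - count]
        for p in fresh:
            out[p] = c
        count += len(fresh)
    return count


def achieved_density(ann: AnnotationMask) -> float:
    return float((ann.labels != 0).mean())


def measure_stroke_width(ann: AnnotationMask) -> int:
    """Modal perpendicular stroke width, estimated per connected stroke as
    the ratio of stroke area to stroke spine length."""
    mask = ann.labels != 0
    labeled, n = ndi.label(mask, structure=np.ones((3, 3)))
    widths = []
    for i in range(1, n + 1):
        comp = labeled == i
        spine = skeletonize(comp)
        s = int(spine.sum())
        if s >= 3:  # ignore specks
            widths.append(int(round(comp.sum() / s)))
    if not widths:
        raise ValueError("no strokes found")
    vals, counts = np.unique(widths, return_counts=True)
    return int(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


def instance_to_semantic(instance_mask: np.ndarray) -> np.ndarray:
    """Collapse instance ids to a two-class semantic mask.

    All ids > 0 become foreground (class 1); background becomes class 2 so
    that it is itself annotatable in scribble space (0 is reserved for
    "unannotated").
    """
    instance_mask = np.asarray(instance_mask)
    if instance_mask.min(initial=0) < 0:
        raise ValueError("instance ids must be >= 0")
    out = np.where(instance_mask > 0, 1, 2)
    return out.astype(np.int32)


def filter_dataset(
    masks: Sequence[np.ndarray],
    rules: Sequence = ("require_class0", "multi_class_only", ("min_class_area", 0.01)),
):
    """Apply exclusion rules to label masks.

    Returns ``(kept_indices, exclusion_log)`` where the log maps mask index
    to a reason code.  Rules: ``require_class0`` drops masks with no class-0
    pixels (incomplete annotations); ``multi_class_only`` drops single-class
    masks; ``("min_class_area", f)`` drops masks where any present class
    covers less than fraction ``f``.
    """
    kept: list[int] = []
    log: dict[int, str] = {}
    for i, mask in enumerate(masks):
        mask = np.asarray(mask)
        reason = None
        for rule in rules:
            if rule == "require_class0":
                if not np.any(mask == 0):
                    reason = "no_class0"
                    break
            elif rule == "multi_class_only":
                if np.unique(mask).size < 2:
                    reason = "single_class"
                    break
            else:
                name, frac = rule
                if name != "min_class_area":
                    raise ValueError(f"unknown rule {rule!r}")
                fracs = np.bincount(mask.ravel()) / mask.size
                present = np.nonzero(fracs)[0]
                if np.any(fracs[present] < frac):
                    reason = "min_class_area"
                    break
        if reason is None:
            kept.append(i)
        else:
            log[i] = reason
    return kept, log


def window_side(dimension: int, min_side: int) -> int:
    """Largest proper divisor of ``dimension`` in ``[min_side, dimension)``;
    falls back to the full dimension when none exists."""
    if min_side < 1:
        raise ValueError("min_side must be >= 1")
    best = dimension
    for d in range(min_side, dimension):
        if dimension % d == 0:
            best = d  # keep scanning upward: want the largest proper divisor
    return best


def window_image(shape: Sequence[int], min_side: int = 1400) -> tuple[int, ...]:
    """Window side per dimension; windows partition the image exactly."""
    return tuple(window_side(int(s), min_side) for s in shape)


def split_windows(mask: np.ndarray, min_side: int = 1400) -> list[np.ndarray]:
    wy, wx = window_image(mask.shape[:2], min_side)
    out = []
    for y0 in range(0, mask.shape[0], wy):
        for x0 in range(0, mask.shape[1], wx):
            out.append(mask[y0 : y0 + wy, x0 : x0 + wx])
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def compute_miou(
    pred: np.ndarray,
    gt: np.ndarray,
    exclude: np.ndarray | None = None,
) -> tuple[float, dict[int, float]]:
    """Mean intersection-over-union over classes present in gt or pred.

    ``exclude`` optionally removes pixels (e.g. scribbled ones) from the
    count.  Returns ``(miou, {class: iou})``.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        pred, gt = pred[keep], gt[keep]
    classes = np.union1d(np.unique(pred), np.unique(gt))
    if classes.size == 0:
        raise ValueError("no classes present in either mask")
    per_class: dict[int, float] = {}
    for c in classes:
        p, g = pred == c, gt == c
        union = int(np.count_nonzero(p | g))
        inter = int(np.count_nonzero(p & g))
        per_class[int(c)] = inter / union if union else 0.0
    return float(np.mean(list(per_class.values()))), per_class


# ---------------------------------------------------------------------------
# Benchmark runner
# ---------------------------------------------------------------------------


def run_benchmark(
    items: Sequence[tuple[str, ImageStack, np.ndarray]],
    specs: Mapping[str, ExtractorSpec],
    levels: Sequence[float] = BENCHMARK_DENSITIES,
    seeds: Sequence[int] = (0,),
    scribble_template: ScribbleConfig | None = None,
    classifier_kind: str = "gradient_boosted_trees",
    normalization: NormalizationConfig | None = None,
    exclude_scribbles: bool = False,
    balanced: bool = False,
):
    """Scribble -> train -> predict -> score over the full cartesian grid.

    ``items`` are ``(image_id, stack, gt_mask)`` triples with 2D ground
    truth.  Returns a pandas DataFrame of BenchmarkRecords; per-item failures
    are logged into the ``error`` column and the run continues.
    """
    import pandas as pd

    from .train import predict_image, sample_training_set, train_classifier

    template = scribble_template or ScribbleConfig()
    records = []
    for image_id, stack, gt in items:
        for spec_name, spec in specs.items():
            for level in levels:
                for seed in seeds:
                    rec: dict = {
                        "image_id": image_id,
                        "extractor": spec_name,
                        "density": level,
                        "seed": seed,
                    }
                    try:
                        cfg = replace(template, density=level, seed=seed)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            ann = generate_scribbles(gt, cfg)
                        rec["achieved_density"] = achieved_density(ann)
                        t0 = time.perf_counter()
                        ts = sample_training_set(stack, ann, spec)
                        t1 = time.perf_counter()
                        model = train_classifier(
                            ts, kind=classifier_kind, seed=seed,
                            normalization=normalization, balanced=balanced,
                        )
                        t2 = time.perf_counter()
                        pred = predict_image(stack.plane(0), model)
                        t3 = time.perf_counter()
                        miou, per_class = compute_miou(
                            pred, gt,
                            exclude=(ann.labels != 0) if exclude_scribbles else None,
                        )
                        rec.update(
                            miou=miou,
                            feature_time=t1 - t0,
                            train_time=t2 - t1,
                            predict_time=t3 - t2,
                            error="",
                        )
                        for c, iou in per_class.items():
                            rec[f"iou_class_{c}"] = iou
                    except Exception as exc:  # per-item failures don't stop the run
                        rec.update(miou=np.nan, error=str(exc))
                    records.append(rec)
    return pd.DataFrame.from_records(records)
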