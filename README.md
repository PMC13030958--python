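# scribseg

Interactive pixel classification from sparse scribble annotations, with
pluggable feature extractors, exact tiled prediction, and a benchmark
pipeline that synthesizes human-like scribbles from ground-truth masks and
scores segmentations by mean intersection-over-union (mIoU).

## What's inside

- **core** (`scribseg.core`) — domain types (`ImageStack` with declared axis
  roles, `AnnotationMask`, `ExtractorSpec`, `TrainedModel`), percentile
  intensity normalization (per plane or per stack, per channel), and model
  persistence as a single `.pseg` archive (JSON manifest + classifier blob).
- **feature extractors** (`scribseg.features`) —
  - `gaussian_baseline`: raw intensity + Gaussian smoothing (default σ = 3);
  - `filterbank`: the classical bank (Gaussian, Laplacian of Gaussian,
    gradient magnitude, difference of Gaussians, structure-tensor and
    Hessian eigenvalues) over σ ∈ {0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0};
  - `cnn_pyramid`: a featurized image pyramid over a convolutional backbone
    (downscale → forward → upscale → concatenate across layers and scales);
  - `vit_patch`: patch-embedding features (14 px / 384-d small variant,
    16 px / 1024-d large variant) upsampled to pixel resolution;
  - `combined`: channel-wise concatenation of any extractors;
  - `multiprojection`: a 2D extractor applied along xy/xz/yz slicings of a
    3D volume (3× channels).

  Backbones are *providers*: the built-ins are tiny seeded random numpy
  architectures with the declared geometry; pretrained networks can be
  plugged in through `register_cnn_backend` / `register_vit_backend`.
  Every local extractor declares an exact **context margin**: features on a
  crop padded by the margin are bit-identical to full-image features.
- **training / prediction** (`scribseg.train`) — training sets sampled only
  from annotation bounding crops (padded by the context margin), gradient
  boosted trees (default) or random forests, per-plane streaming stack
  prediction, downscale-then-majority-filter prediction.
- **tiling** (`scribseg.tiling`) — exact tiled prediction: with margin ≥
  context margin the tiled result is bit-identical to untiled, independent
  of worker count. Whole-image-context extractors (ViT) refuse tiling unless
  explicitly overridden.
- **benchmark** (`scribseg.bench`) — scribble synthesis from ground truth
  (center-ridge, boundary-parallel and boundary-perpendicular lines sampled
  from primary/secondary skeletons), annotation-density calibration
  (benchmark levels 0.25% / 1.0% / 2.5%), style presets (cell: short 1-px;
  natural: long 2-px; histology: medium 2-px), dataset filtering and
  windowing rules, mIoU scoring, and a seeded benchmark runner.
- **synthetic data** (`scribseg.synth`) — seeded fixtures: intensity- and
  texture-separable images, a semantic-context fixture (classes locally
  identical, distinguishable only via large-scale context), instance masks,
  3D volumes, and multichannel images where only joint channel statistics
  are informative.

## CLI

```bash
# generate synthetic fixture images + manifest
scribseg fixtures -o fixtures/ --kinds intensity_separable,texture_separable --seed 0

# synthesize scribbles from a ground-truth mask
scribseg scribble fixtures/intensity_separable_gt.tif -o scrib.tif --density 0.01 --seed 0

# train (writes model.pseg + a replayable .runconfig.json sidecar)
scribseg train fixtures/intensity_separable_img.tif scrib.tif -o model.pseg \
    --extractor filterbank --seed 0

# predict (optionally tiled and/or downscaled + majority-filtered)
scribseg predict fixtures/intensity_separable_img.tif -m model.pseg -o labels.tif \
    --tile-size 512 --workers 4

# benchmark a fixtures directory
scribseg bench fixtures/ -o bench.csv --extractors filterbank,gaussian_baseline \
    --levels 0.0025,0.01,0.025 --seeds 0
```

Tiling flags: `--tile-size`, `--tile-margin` (default: the extractor's exact
context margin), `--workers`, `--allow-tiling-global-context`.

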