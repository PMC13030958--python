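"""Readers and writers for intensity images, label images, and zarr stores.

Axis inference for the CLI: explicit axes win; otherwise rank 2 -> (y, x),
rank 3 -> (plane, y, x) unless the leading extent is <= 4, in which case it
is treated as channels; rank 4 -> (plane, channel, y, x).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core import ImageStack


def infer_axes(shape: tuple[int, ...]) -> tuple[str, ...]:
    if len(shape) == 2:
        return ("y", "x")
    if len(shape) == 3:
        return ("channel", "y", "x") if shape[0] <= 4 else ("plane", "y", "x")
    if len(shape) == 4:
        return ("plane", "channel", "y", "x")
    raise ValueError(f"cannot infer axes for a rank-{len(shape)} array")


def read_array(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    if suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # PNG loads (H, W, C); move channels first
            arr = np.moveaxis(arr, -1, 0)
        return arr
    if suffix == ".zarr" or path.is_dir():
        import zarr

        return zarr.open_array(str(path), mode="r")[:]
    raise ValueError(f"unsupported image format: {path}")


def read_stack(path, axes: tuple[str, ...] | None = None) -> ImageStack:
    arr = read_array(path)
    return ImageStack(data=arr, axes=axes or infer_axes(arr.shape))


def read_labels(path) -> np.ndarray:
    arr = np.asarray(read_array(path))
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"label image {path} has non-integer values")
        arr = np.round(arr).astype(np.int32)
    return arr.astype(np.int32)


def write_image(path, array: np.ndarray) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, array)
        return
    if suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(array)
        if arr.ndim == 3:
            arr = np.moveaxis(arr, 0, -1)
        iio.imwrite(path, arr)
        return
    if suffix == ".zarr":
        import zarr

        z = zarr.open_array(
            str(path), mode="w", shape=array.shape, dtype=array.dtype
        )
        z[:] = array
        return
    raise ValueError(f"unsupported image format: {path}")


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0:
        raise ValueError("labels must be non-negative")
    dtype = np.uint8 if labels.max(initial=0) < 256 else np.uint16
    write_image(path, labels.astype(dtype))
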