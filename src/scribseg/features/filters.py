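"""Hand-crafted filter extractors: Gaussian baseline and the classical bank.

All filters run in float64 with reflective ("symmetric") boundary handling and
a fixed Gaussian truncation of 4 sigma, so features computed on a crop padded
by the extractor's context margin are bit-identical to full-image features.

Filter bank channel layout (documented contract):

    [raw intensity per input channel]
    then, for each input channel, for each sigma in order:
        0. Gaussian
        1. Laplacian of Gaussian
        2. Gaussian gradient magnitude
        3. Difference of Gaussians  (G(sigma) - G(0.66 * sigma))
        4. structure tensor eigenvalue, larger
        5. structure tensor eigenvalue, smaller
        6. Hessian of Gaussian eigenvalue, larger
        7. Hessian of Gaussian eigenvalue, smaller

Structure tensor: gradients at ``sigma``, tensor smoothed at ``sigma / 2``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

TRUNCATE = 4.0
DOG_RATIO = 0.66

#: Maximal sigma set suggested for the classical bank.
DEFAULT_SIGMAS = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)

#: Baseline smoothing scale.
DEFAULT_BASELINE_SIGMA = 3.0

FILTERS_PER_SIGMA = 8


def kernel_radius(sigma: float) -> int:
    """Support radius of a truncated Gaussian kernel (matches scipy)."""
    return int(TRUNCATE * sigma + 0.5)


def _check_plane(plane: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim == 2:
        plane = plane[np.newaxis]
    if plane.ndim != 3:
        raise ValueError("expected a (C, H, W) or (H, W) plane")
    if plane.shape[1] < 2 or plane.shape[2] < 2:
        raise ValueError("filters are undefined on images smaller than 2x2")
    return plane


def _gauss(img: np.ndarray, sigma: float, order=(0, 0)) -> np.ndarray:
    return ndi.gaussian_filter(
        img, sigma, order=order, mode="reflect", truncate=TRUNCATE
    )


def _sorted_eigs_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Eigenvalues of the symmetric matrix [[a, b], [b, c]], descending."""
    tr = a + c
    disc = np.sqrt((a - c) ** 2 + 4.0 * b**2)
    return (tr + disc) / 2.0, (tr - disc) / 2.0


def gaussian_baseline_channels(
    plane: np.ndarray, sigma: float = DEFAULT_BASELINE_SIGMA
) -> np.ndarray:
    """Raw intensity plus one Gaussian-smoothed channel per input channel."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    plane = _check_plane(plane)
    smoothed = [_gauss(ch, sigma) for ch in plane]
    return np.concatenate([plane, np.stack(smoothed)], axis=0)


def filterbank_channels(
    plane: np.ndarray, sigmas: Sequence[float] = DEFAULT_SIGMAS
) -> np.ndarray:
    """Evaluate the classical filter bank; see module docstring for layout."""
    sigmas = tuple(float(s) for s in sigmas)
    if not sigmas:
        raise ValueError("sigma list must be non-empty")
    if any(s <= 0 for s in sigmas):
        raise ValueError("all sigmas must be strictly positive")
    plane = _check_plane(plane)

    out: list[np.ndarray] = [ch for ch in plane]
    for ch in plane:
        for sigma in sigmas:
            gauss = _gauss(ch, sigma)
            log = ndi.gaussian_laplace(ch, sigma, mode="reflect", truncate=TRUNCATE)
            gy = _gauss(ch, sigma, order=(1, 0))
            gx = _gauss(ch, sigma, order=(0, 1))
            gradmag = np.sqrt(gy**2 + gx**2)
            dog = gauss - _gauss(ch, DOG_RATIO * sigma)
            # structure tensor: gradients at sigma, integration at sigma / 2
            si = sigma / 2.0
            sxx = _gauss(gx * gx, si)
            sxy = _gauss(gx * gy, si)
            syy = _gauss(gy * gy, si)
            st_hi, st_lo = _sorted_eigs_2x2(sxx, sxy, syy)
            hyy = _gauss(ch, sigma, order=(2, 0))
            hxx = _gauss(ch, sigma, order=(0, 2))
            hxy = _gauss(ch, sigma, order=(1, 1))
            h_hi, h_lo = _sorted_eigs_2x2(hxx, hxy, hyy)
            out.extend([gauss, log, gradmag, dog, st_hi, st_lo, h_hi, h_lo])
    return np.stack(out)


def gaussian_baseline_margin(sigma: float) -> int:
    return kernel_radius(sigma)


def filterbank_margin(sigmas: Sequence[float]) -> int:
    """Exact worst-case support radius over all filters in the bank.

    The structure tensor cascades two Gaussian passes (gradient then
    integration), so its support is the sum of the two kernel radii and
    dominates the simple 4-sigma rule.
    """
    margin = 0
    for s in sigmas:
        candidates = (
            kernel_radius(s),
            kernel_radius(DOG_RATIO * s),
            kernel_radius(s) + kernel_radius(s / 2.0),
        )
        margin = max(margin, *candidates)
    return margin


def gaussian_baseline_n_channels(n_input_channels: int) -> int:
    return 2 * n_input_channels


def filterbank_n_channels(n_input_channels: int, n_sigmas: int) -> int:
    return n_input_channels * (1 + FILTERS_PER_SIGMA * n_sigmas)
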