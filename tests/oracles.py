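"""Independent brute-force oracles used by the test suite.

The filter oracle builds explicit sampled Gaussian-derivative kernels, pads
images by iterated half-sample mirroring, and evaluates dense 2D convolutions
with a sliding-window einsum — a completely separate code path from the
package's separable scipy.ndimage implementation.  Eigenvalues come from
``np.linalg.eigvalsh`` per pixel rather than the closed form.
"""

from __future__ import annotations

import numpy as np

TRUNCATE = 4.0
DOG_RATIO = 0.66


def kernel_1d(sigma: float, order: int = 0) -> np.ndarray:
    """Sampled Gaussian (or derivative) kernel, truncated at 4 sigma."""
    r = int(TRUNCATE * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=np.float64)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / sigma**2 * phi
    if order == 2:
        return (x**2 / sigma**4 - 1.0 / sigma**2) * phi
    raise ValueError(order)


def pad_reflect(img: np.ndarray, r: int) -> np.ndarray:
    """Half-sample symmetric padding by r pixels, iterated so r may exceed
    the image size (matches scipy.ndimage mode='reflect')."""
    out = img
    remaining = r
    # pad in steps of the original size so intermediate edges stay on mirror
    # planes of the infinite half-sample symmetric extension
    n = min(img.shape)
    while remaining > 0:
        step = min(remaining, n)
        out = np.pad(out, step, mode="symmetric")
        remaining -= step
    return out


def dense_conv(img: np.ndarray, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
    """Dense 2D convolution with the separable kernel ky (x) kx, reflective
    boundaries, same output size."""
    k2 = np.outer(ky, kx)
    ry, rx = len(ky) // 2, len(kx) // 2
    r = max(ry, rx)
    padded = pad_reflect(np.asarray(img, dtype=np.float64), r)
    if ry < r:
        padded = padded[r - ry : padded.shape[0] - (r - ry), :]
    if rx < r:
        padded = padded[:, r - rx : padded.shape[1] - (r - rx)]
    windows = np.lib.stride_tricks.sliding_window_view(padded, k2.shape)
    return np.einsum("ijkl,kl->ij", windows, k2)


def eig_desc(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Per-pixel eigenvalues of [[a, b], [b, c]] via np.linalg.eigvalsh."""
    h, w = a.shape
    hi = np.empty((h, w))
    lo = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            vals = np.linalg.eigvalsh(
                np.array([[a[i, j], b[i, j]], [b[i, j], c[i, j]]])
            )
            lo[i, j], hi[i, j] = vals
    return hi, lo


def filterbank_oracle(img: np.ndarray, sigma: float) -> dict[str, np.ndarray]:
    """All eight filter responses for one channel at one sigma."""
    g0 = kernel_1d(sigma, 0)
    g1 = kernel_1d(sigma, 1)
    g2 = kernel_1d(sigma, 2)
    out: dict[str, np.ndarray] = {}
    out["gauss"] = dense_conv(img, g0, g0)
    out["log"] = dense_conv(img, g2, g0) + dense_conv(img, g0, g2)
    gy = dense_conv(img, g1, g0)
    gx = dense_conv(img, g0, g1)
    out["gradmag"] = np.sqrt(gy**2 + gx**2)
    gi = kernel_1d(DOG_RATIO * sigma, 0)
    out["dog"] = out["gauss"] - dense_conv(img, gi, gi)
    si = kernel_1d(sigma / 2.0, 0)
    sxx = dense_conv(gx * gx, si, si)
    sxy = dense_conv(gx * gy, si, si)
    syy = dense_conv(gy * gy, si, si)
    out["st_hi"], out["st_lo"] = eig_desc(sxx, sxy, syy)
    hyy = dense_conv(img, g2, g0)
    hxx = dense_conv(img, g0, g2)
    hxy = dense_conv(img, g1, g1)
    out["h_hi"], out["h_lo"] = eig_desc(hxx, hxy, hyy)
    return out


FILTER_ORDER = ("gauss", "log", "gradmag", "dog", "st_hi", "st_lo", "h_hi", "h_lo")


def gaussian_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    g0 = kernel_1d(sigma, 0)
    return dense_conv(img, g0, g0)


def miou_oracle(pred: np.ndarray, gt: np.ndarray):
    """Brute-force double-loop counting of per-class IoU."""
    classes = sorted(set(np.unique(pred)) | set(np.unique(gt)))
    ious = {}
    for c in classes:
        inter = union = 0
        for i in range(pred.shape[0]):
            for j in range(pred.shape[1]):
                p = pred[i, j] == c
                g = gt[i, j] == c
                inter += p and g
                union += p or g
        ious[int(c)] = inter / union if union else 0.0
    return sum(ious.values()) / len(ious), ious


def percentile_oracle(values: np.ndarray, q: float) -> float:
    """Sort-based linear-interpolation percentile (independent of numpy)."""
    v = sorted(np.asarray(values, dtype=float).ravel())
    n = len(v)
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def majority_oracle(labels: np.ndarray, r: int) -> np.ndarray:
    """Direct modal computation per pixel; ties keep the center label if
    tied, else the lowest tied label."""
    h, w = labels.shape
    out = np.empty_like(labels)
    for i in range(h):
        for j in range(w):
            window = labels[max(i - r, 0) : i + r + 1, max(j - r, 0) : j + r + 1]
            vals, counts = np.unique(window, return_counts=True)
            m = counts.max()
            tied = vals[counts == m]
            center = labels[i, j]
            out[i, j] = center if center in tied else tied.min()
    return out
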