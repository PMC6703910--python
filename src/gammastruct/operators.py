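"""Focus-measure operators quantifying the relative degree of focus (RDF).

Each operator maps a grayscale luminance image (2-D float array in [0, 1])
to a nonnegative-ish scalar that grows with the amount of sharp structure.
The suite follows the shape-from-focus literature: gradient-, Laplacian-,
statistics-, DCT- and wavelet-based families plus a few miscellaneous
measures.  Operators that produce a pixel-level focus map are pooled by the
mean over the evaluated region; operators whose classical definition is a
single region statistic (e.g. gray-level variance) return it directly.

Conventions chosen where the literature leaves them open:
- local windows are 3x3 (5x5 for the Helmli mean-ratio measure),
- DCT operators use non-overlapping 8x8 blocks,
- wavelet operators use a single db6 decomposition level,
- convolution boundaries are replicated (``mode="nearest"``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.fft import dctn
import pywt

__all__ = ["OPERATORS", "apply_operator", "operator_ids"]

_WAVELET = "db6"


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D luminance image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def _conv(img, kernel):
    return ndimage.convolve(img, np.asarray(kernel, dtype=np.float64), mode="nearest")


# -- statistics-based ---------------------------------------------------------

def gray_level_variance(img):
    return float(np.var(img))


def gray_level_local_variance(img):
    # variance of the 3x3 local-variance map (Pech-Pacheco et al.)
    mean = ndimage.uniform_filter(img, size=3, mode="nearest")
    sq = ndimage.uniform_filter(img * img, size=3, mode="nearest")
    local_var = np.maximum(sq - mean * mean, 0.0)
    return float(np.var(local_var))


def gray_level_variance_normalized(img):
    mu = float(np.mean(img))
    if mu <= 0:
        return 0.0
    return float(np.var(img) / mu)


def abs_central_moment(img):
    # histogram-based absolute central moment over 256 gray levels
    hist, edges = np.histogram(img, bins=256, range=(0.0, 1.0))
    p = hist / max(hist.sum(), 1)
    levels = 0.5 * (edges[:-1] + edges[1:])
    mu = float(np.sum(levels * p))
    return float(np.sum(np.abs(levels - mu) * p))


# -- gradient-based -----------------------------------------------------------

def brenner(img):
    """Max of squared horizontal/vertical gray-level differences at lag 2."""
    return float(np.mean(brenner_map(img)))


def brenner_map(img):
    img = _as_float(img)
    h = (img[:, 2:] - img[:, :-2]) ** 2
    v = (img[2:, :] - img[:-2, :]) ** 2
    n = min(h.shape[0], v.shape[0])
    m = min(h.shape[1], v.shape[1])
    return np.maximum(h[:n, :m], v[:n, :m])


def squared_gradient(img):
    h = (img[:, 1:] - img[:, :-1]) ** 2
    v = (img[1:, :] - img[:-1, :]) ** 2
    return float(0.5 * (np.mean(h) + np.mean(v)))


def thresholded_gradient(img, threshold: float = 0.0):
    h = np.abs(img[:, 1:] - img[:, :-1])
    v = np.abs(img[1:, :] - img[:-1, :])
    g = np.concatenate([h.ravel(), v.ravel()])
    g = np.where(g >= threshold, g, 0.0)
    return float(np.mean(g))


def energy_of_gradient(img):
    h = img[:, 1:] - img[:, :-1]
    v = img[1:, :] - img[:-1, :]
    return float(np.mean(h * h) + np.mean(v * v))


def tenengrad(img):
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    return float(np.mean(gx * gx + gy * gy))


def tenengrad_variance(img):
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    return float(np.var(gx * gx + gy * gy))


def gaussian_derivative(img, sigma: float = 1.0):
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    return float(np.mean(gx * gx + gy * gy))


# -- Laplacian-based ----------------------------------------------------------

_LAP = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
_LX = np.array([[-1.0, 2.0, -1.0]])
_LY = _LX.T
_S2 = np.sqrt(2.0)
_LD1 = np.array([[0.0, 0.0, -1.0], [0.0, 2.0, 0.0], [-1.0, 0.0, 0.0]]) / _S2
_LD2 = np.array([[-1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, -1.0]]) / _S2


def energy_of_laplacian(img):
    lap = _conv(img, _LAP)
    return float(np.mean(lap * lap))


def modified_laplacian(img):
    return float(np.mean(np.abs(_conv(img, _LX)) + np.abs(_conv(img, _LY))))


def variance_of_laplacian(img):
    return float(np.var(_conv(img, _LAP)))


def diagonal_laplacian(img):
    m = (np.abs(_conv(img, _LX)) + np.abs(_conv(img, _LY))
         + np.abs(_conv(img, _LD1)) + np.abs(_conv(img, _LD2)))
    return float(np.mean(m))


# -- DCT-based ----------------------------------------------------------------

def _dct_blocks(img, block: int = 8):
    h, w = img.shape
    nh, nw = h // block, w // block
    if nh == 0 or nw == 0:
        raise ValueError(
            f"image {img.shape} too small for {block}x{block} DCT blocks")
    img = img[: nh * block, : nw * block]
    blocks = img.reshape(nh, block, nw, block).transpose(0, 2, 1, 3)
    return dctn(blocks, axes=(-2, -1), norm="ortho")


def dct_energy(img):
    """Mean AC energy of 8x8 DCT blocks."""
    coefs = _dct_blocks(img)
    energy = coefs * coefs
    ac = energy.sum(axis=(-2, -1)) - energy[..., 0, 0]
    return float(np.mean(ac))


def dct_energy_ratio(img):
    """Mean ratio of AC to DC energy in 8x8 DCT blocks."""
    coefs = _dct_blocks(img)
    energy = coefs * coefs
    dc = energy[..., 0, 0]
    ac = energy.sum(axis=(-2, -1)) - dc
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dc > 0, ac / dc, 0.0)
    return float(np.mean(ratio))


# -- wavelet-based ------------------------------------------------------------

def _dwt_details(img):
    _, (ch, cv, cd) = pywt.dwt2(img, _WAVELET, mode="symmetric")
    return ch, cv, cd


def wavelet_sum(img):
    ch, cv, cd = _dwt_details(img)
    return float(np.mean(np.abs(ch)) + np.mean(np.abs(cv)) + np.mean(np.abs(cd)))


def wavelet_variance(img):
    ch, cv, cd = _dwt_details(img)
    detail = np.concatenate([ch.ravel(), cv.ravel(), cd.ravel()])
    return float(np.var(detail))


def wavelet_ratio(img):
    ca, (ch, cv, cd) = pywt.dwt2(img, _WAVELET, mode="symmetric")
    e_detail = float(np.sum(ch * ch) + np.sum(cv * cv) + np.sum(cd * cd))
    e_approx = float(np.sum(ca * ca))
    if e_approx <= 0:
        return 0.0
    return e_detail / e_approx


# -- miscellaneous ------------------------------------------------------------

def image_contrast(img):
    # mean absolute difference to the 8-neighborhood
    total = np.zeros_like(img)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            total += np.abs(img - shifted)
    # roll wraps at the border; evaluate the interior only
    return float(np.mean(total[1:-1, 1:-1]))


def image_curvature(img):
    """Local quadratic-surface fit; pooled absolute non-constant coefficients.

    Fits f(x, y) = a + b*x + c*y + d*x^2 + e*y^2 on each 3x3 neighborhood
    (separable least squares on offsets x, y in {-1, 0, 1}) and pools
    |b| + |c| + |d| + |e|, so a constant image scores exactly 0.
    """
    kx = np.array([[-1.0, 0.0, 1.0]]) / 2.0
    b = _conv(img, np.repeat(kx, 3, axis=0) / 3.0)
    c = _conv(img, np.repeat(kx.T, 3, axis=1) / 3.0)
    kq = np.array([[1.0, -2.0, 1.0]]) / 2.0  # curvature along one axis
    d = _conv(img, np.repeat(kq, 3, axis=0) / 3.0)
    e = _conv(img, np.repeat(kq.T, 3, axis=1) / 3.0)
    return float(np.mean(np.abs(b) + np.abs(c) + np.abs(d) + np.abs(e)))


def helmli(img, size: int = 5, floor: float = 0.05):
    """Mean-ratio method: R = max(mean/I, I/mean), pooled; constant image -> 1.

    Luminances are floored at ``floor`` so near-black pixels cannot blow up
    the ratio (the measure is otherwise heavy-tailed and unstable).
    """
    img = np.maximum(img, floor)
    mean = ndimage.uniform_filter(img, size=size, mode="nearest")
    up = mean / img
    dn = img / mean
    return float(np.mean(np.maximum(up, dn)))


def steerable_filters(img, sigma: float = 1.0, n_angles: int = 8):
    # max response over oriented first-order Gaussian derivative filters
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    angles = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    resp = np.stack([np.cos(a) * gx + np.sin(a) * gy for a in angles])
    return float(np.mean(np.max(resp, axis=0)))


def spatial_frequency(img):
    h = img[:, 1:] - img[:, :-1]
    v = img[1:, :] - img[:-1, :]
    return float(np.sqrt(np.mean(h * h) + np.mean(v * v)))


def vollath_autocorrelation(img):
    lag1 = np.mean(img[:, :-1] * img[:, 1:])
    lag2 = np.mean(img[:, :-2] * img[:, 2:])
    return float(lag1 - lag2)


OPERATORS = {
    "abs_central_moment": abs_central_moment,
    "brenner": brenner,
    "image_contrast": image_contrast,
    "image_curvature": image_curvature,
    "dct_energy": dct_energy,
    "dct_energy_ratio": dct_energy_ratio,
    "gaussian_derivative": gaussian_derivative,
    "gray_level_variance": gray_level_variance,
    "gray_level_local_variance": gray_level_local_variance,
    "gray_level_variance_normalized": gray_level_variance_normalized,
    "energy_of_gradient": energy_of_gradient,
    "thresholded_gradient": thresholded_gradient,
    "squared_gradient": squared_gradient,
    "helmli": helmli,
    "energy_of_laplacian": energy_of_laplacian,
    "modified_laplacian": modified_laplacian,
    "variance_of_laplacian": variance_of_laplacian,
    "diagonal_laplacian": diagonal_laplacian,
    "steerable_filters": steerable_filters,
    "spatial_frequency": spatial_frequency,
    "tenengrad": tenengrad,
    "tenengrad_variance": tenengrad_variance,
    "vollath_autocorrelation": vollath_autocorrelation,
    "wavelet_sum": wavelet_sum,
    "wavelet_variance": wavelet_variance,
    "wavelet_ratio": wavelet_ratio,
}


def operator_ids() -> list[str]:
    """The 26 operator identifiers, in canonical order."""
    return list(OPERATORS)


def apply_operator(image: np.ndarray, operator_id: str) -> float:
    """Apply one focus-measure operator to a luminance image region."""
    try:
        fn = OPERATORS[operator_id]
    except KeyError:
        raise KeyError(
            f"unknown operator {operator_id!r}; valid ids: {sorted(OPERATORS)}"
        ) from None
    return fn(_as_float(image))
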