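"""Relative-degree-of-focus (RDF) scoring of luminance images.

Global RDF is computed on the central 80% of the image (10% trimmed from
every edge, to avoid boundary effects of the operators); patch-wise RDF
scans the full image with a 19x19 grid of square patches, each spanning
0.1 of the image edge, stepped by 0.05 of the edge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .operators import OPERATORS, apply_operator, operator_ids

__all__ = [
    "DEFAULT_OPERATOR",
    "central_crop",
    "compute_rdf",
    "compute_rdf_all",
    "patchwise_rdf",
    "patch_grid",
    "rank_images",
    "rdf_table",
]

#: operator used throughout the headline analyses
DEFAULT_OPERATOR = "dct_energy"

PATCH_GRID_SIZE = 19
PATCH_FRACTION = 0.1
PATCH_STEP_FRACTION = 0.05


def _check_image(image: np.ndarray, min_size: int = 16) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {image.shape}")
    if min(image.shape) < min_size:
        raise ValueError(
            f"image {image.shape} smaller than required {min_size}x{min_size}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def central_crop(image: np.ndarray, fraction: float = 0.8) -> np.ndarray:
    """Central ``fraction`` of the image in both dimensions."""
    h, w = image.shape
    dy = int(round(h * (1 - fraction) / 2))
    dx = int(round(w * (1 - fraction) / 2))
    return image[dy:h - dy, dx:w - dx]


def compute_rdf(image: np.ndarray, operator_id: str = DEFAULT_OPERATOR) -> float:
    """Global RDF score of an image: operator applied to the central-80% crop."""
    image = _check_image(image)
    return apply_operator(central_crop(image), operator_id)


def compute_rdf_all(image: np.ndarray) -> dict[str, float]:
    """All 26 operator scores for one image (central-80% crop)."""
    image = _check_image(image)
    crop = central_crop(image)
    return {op: apply_operator(crop, op) for op in OPERATORS}


def patch_grid(edge: int) -> tuple[np.ndarray, int]:
    """Patch start offsets (19 per dimension) and patch size in pixels."""
    fracs = np.arange(PATCH_GRID_SIZE) * PATCH_STEP_FRACTION
    starts = np.round(fracs * edge).astype(int)
    size = int(round(PATCH_FRACTION * edge))
    return starts, size


def patchwise_rdf(image: np.ndarray,
                  operator_id: str = DEFAULT_OPERATOR) -> np.ndarray:
    """19x19 map of patch RDF scores.

    Patches span 0.1 of the edge length, stepped by 0.05, so the grid covers
    the full image; no central crop is applied inside patches.
    """
    image = _check_image(image, min_size=20)
    h, w = image.shape
    ys, ph = patch_grid(h)
    xs, pw = patch_grid(w)
    out = np.empty((PATCH_GRID_SIZE, PATCH_GRID_SIZE))
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            out[i, j] = apply_operator(image[y:y + ph, x:x + pw], operator_id)
    return out


def patch_disc_mask(edge: int, center_frac, radius_frac: float) -> np.ndarray:
    """Grid mask of patches whose window intersects a visual-field disc.

    ``center_frac`` is the disc center in image fractions (x, y); a patch
    counts as covering the disc if any point of its square window lies
    within ``radius_frac`` of the center.  Useful for comparing patch-wise
    correlation maps against a known receptive-field disc.
    """
    starts, size = patch_grid(edge)
    x0, y0 = (np.asarray(center_frac, dtype=np.float64) * edge)
    r = radius_frac * edge
    out = np.zeros((PATCH_GRID_SIZE, PATCH_GRID_SIZE), dtype=bool)
    for i, ys in enumerate(starts):
        dy = max(ys - y0, y0 - (ys + size), 0.0)
        for j, xs in enumerate(starts):
            dx = max(xs - x0, x0 - (xs + size), 0.0)
            out[i, j] = dx * dx + dy * dy <= r * r
    return out


def rank_images(scores) -> np.ndarray:
    """Ascending ranks 1..N with average ranks for ties (lowest RDF -> rank 1)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need a 1-D array of at least two scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return rankdata(scores, method="average")


def rdf_table(images, operators=None, image_ids=None) -> pd.DataFrame:
    """Long-format table of global RDF scores (image_id, operator, score)."""
    if operators is None:
        operators = operator_ids()
    if image_ids is None:
        image_ids = range(len(images))
    rows = []
    for iid, img in zip(image_ids, images):
        crop = central_crop(_check_image(img))
        for op in operators:
            rows.append((iid, op, apply_operator(crop, op)))
    return pd.DataFrame(rows, columns=["image_id", "operator", "score"])
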