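"""GLCM-based fluorescence homogeneity score for cell-contact images.

A spatially even fluorescence signal at the cell-coverslip contact (e.g. a
membrane flattened onto the coating) produces many equal-gray neighbouring
pixel pairs, while a ruffled contact produces dissimilar pairs. The score
captures this with the gray-level co-occurrence matrix (GLCM):

1. convert the image to 8-bit gray values (min-max rescale),
2. zero every pixel below the ISODATA threshold (background removal),
3. build the 256 x 256 GLCM at offset 1 for the four directions
   0, pi/4, pi/2 and 3pi/4,
4. zero the first row and column (pairs involving background),
   normalize the matrix to sum 1,
5. weight each entry by 1/(1 + |i - j|) and sum -> per-angle homogeneity,
6. average the four angles.

The score lies in [0, 1]; it is 1 exactly when every counted pair has equal
gray levels in all four directions. Directions whose matrix is empty after
background zeroing contribute 0 instead of aborting. The squared-difference
weight 1/(1 + (i - j)^2) is available as an alternative.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

__all__ = [
    "ANGLES",
    "to_gray8",
    "isodata_threshold",
    "compute_glcm",
    "homogeneity_score",
]

#: GLCM directions: horizontal, diagonal, vertical, anti-diagonal
ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def to_gray8(img: np.ndarray) -> np.ndarray:
    """Convert an image to 8-bit gray levels by min-max rescaling.

    ``uint8`` input is returned unchanged; anything else is rescaled to
    span 0..255 (a constant image maps to 0).
    """
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def isodata_threshold(img: np.ndarray) -> float:
    """ISODATA threshold: fixed point of the sub/supra-mean midpoint.

    Starting from the mid-range value, the threshold T is iterated to the
    midpoint of the mean gray value below T and the mean at or above T
    until convergence. Raises on a constant image (threshold undefined).
    Applied by the homogeneity pipeline as: values strictly below T -> 0.
    """
    v = np.asarray(img, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant image: ISODATA threshold undefined")
    t = 0.5 * (lo + hi)
    for _ in range(500):
        below = v[v < t]
        above = v[v >= t]
        if len(below) == 0 or len(above) == 0:
            # threshold fell outside the occupied gray range; nudge to the
            # midpoint of the extremes of the other side
            t_new = 0.5 * (v.min() + v.max())
        else:
            t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-9:
            return float(t_new)
        t = t_new
    return float(t)


def compute_glcm(img: np.ndarray, offset: int = 1,
                 angle: float = 0.0) -> tuple[np.ndarray, bool]:
    """Normalized 256 x 256 co-occurrence matrix for one direction.

    ``img`` must already be 8-bit and background-zeroed. Ordered gray-level
    pairs at the given pixel displacement are counted, entries involving
    gray value 0 (first row and column) are zeroed, and the matrix is
    normalized to sum 1. Returns ``(glcm, empty)`` where ``empty`` flags a
    matrix with no surviving pairs.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("compute_glcm expects an 8-bit image")
    if img.shape[0] < 2 and img.shape[1] < 2:
        raise ValueError("image must be at least 1x2 or 2x1")
    counts = graycomatrix(img, distances=[offset], angles=[angle],
                          levels=256, symmetric=False, normed=False)
    m = counts[:, :, 0, 0].astype(float)
    m[0, :] = 0.0
    m[:, 0] = 0.0
    total = m.sum()
    if total == 0:
        return m, True
    return m / total, False


def homogeneity_score(img: np.ndarray, weight: str = "abs_diff",
                      offset: int = 1) -> float:
    """Average GLCM homogeneity of an image over the four directions.

    ``weight`` selects the entry weight: ``abs_diff`` -> 1/(1 + |i - j|)
    (default), ``sq_diff`` -> 1/(1 + (i - j)^2). See the module docstring
    for the full pipeline.
    """
    if weight not in ("abs_diff", "sq_diff"):
        raise ValueError(f"unknown weight {weight!r}")
    gray = to_gray8(img)
    t = isodata_threshold(gray)
    cleaned = gray.copy()
    cleaned[gray < t] = 0
    i, j = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
    if weight == "abs_diff":
        w = 1.0 / (1.0 + np.abs(i - j))
    else:
        w = 1.0 / (1.0 + (i - j) ** 2)
    values = []
    for angle in ANGLES:
        m, empty = compute_glcm(cleaned, offset=offset, angle=angle)
        values.append(0.0 if empty else float((m * w).sum()))
    return float(np.mean(values))
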