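"""Low-level image primitives shared by the detection chain.

Everything here operates on plain numpy arrays: 8-bit grayscale frames as
``uint8`` 2-D arrays and binary masks as boolean 2-D arrays.  The primitives
are deliberately small and deterministic — fixed luminance weights, an
explicit Otsu tie-break, an explicit origin convention for the even-sized
closing element — so that the downstream behavior rules see reproducible
pixel coordinates.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "LUMA_WEIGHTS",
    "OtsuResult",
    "to_grayscale",
    "median_filter",
    "otsu_threshold",
    "close_binary",
    "fill_holes",
    "remove_small_areas",
    "largest_component",
    "square_element",
]

#: ITU-R BT.601 luminance weights (the classic analog-video convention,
#: also MATLAB's rgb2gray), applied as gray = R*w0 + G*w1 + B*w2.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: 8-connectivity structure for component labeling.
_CONN8 = np.ones((3, 3), dtype=bool)


class OtsuResult(NamedTuple):
    """Threshold level plus a flag marking a degenerate (single-level) histogram."""

    threshold: int
    degenerate: bool


def _as_gray_u8(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("grayscale values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit color frame to grayscale with BT.601 weights.

    Already-grayscale (2-D) input is passed through unchanged, so the
    operation is idempotent.  Any channel count other than 3 is rejected.
    """
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return _as_gray_u8(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W) or (H, W, 3) input, got shape {arr.shape}")
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = arr.astype(np.float64) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def median_filter(frame: np.ndarray, window: int = 3) -> np.ndarray:
    """Square median filter with edge replication at the borders.

    ``window`` must be odd and >= 1 so the window has a center pixel.
    """
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be an odd integer >= 1, got {window!r}")
    arr = _as_gray_u8(frame)
    if window == 1:
        return arr.copy()
    return ndimage.median_filter(arr, size=window, mode="nearest")


def otsu_threshold(frame: np.ndarray) -> OtsuResult:
    """Otsu's threshold: the level t maximizing between-class variance.

    The split is {<= t} vs {> t}; ties are broken toward the smallest
    maximizing t so the result is deterministic.  A constant image has no
    two-class split — its single gray level is returned with
    ``degenerate=True``.
    """
    arr = _as_gray_u8(frame)
    if arr.size == 0:
        raise ValueError("cannot threshold an empty image")
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return OtsuResult(int(nonzero[0]), True)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)  # weight of class {<= t}
    mu = np.cumsum(p * levels)  # first moment of class {<= t}
    mu_total = mu[-1]
    valid = (omega > 0.0) & (omega < 1.0)
    sigma_b = np.full(256, -np.inf)
    num = (mu_total * omega[valid] - mu[valid]) ** 2
    sigma_b[valid] = num / (omega[valid] * (1.0 - omega[valid]))
    return OtsuResult(int(np.argmax(sigma_b)), False)


def square_element(size: int = 4) -> np.ndarray:
    """All-ones square structuring element."""
    if size < 1:
        raise ValueError("element size must be >= 1")
    return np.ones((size, size), dtype=bool)


def close_binary(mask: np.ndarray, element: np.ndarray | None = None) -> np.ndarray:
    """Morphological closing (dilation then erosion) with the same element.

    The default element is the 4x4 square.  Even-sized elements need an
    origin convention: the origin sits at the top-left pixel of the central
    2x2 block, i.e. one pixel up-left of scipy's default center.
    """
    m = np.asarray(mask, dtype=bool)
    el = square_element(4) if element is None else np.asarray(element, dtype=bool)
    if el.size == 0 or not el.any():
        raise ValueError("structuring element must be nonempty")
    origin = tuple(-1 if s % 2 == 0 else 0 for s in el.shape)
    # Outside the image counts as background for the dilation but as
    # foreground for the erosion, so closing never eats the mask at the
    # image border and stays extensive (output >= input).
    dilated = ndimage.binary_dilation(m, structure=el, origin=origin)
    return ndimage.binary_erosion(dilated, structure=el, origin=origin, border_value=1)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def remove_small_areas(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if min_area <= 1 or not m.any():
        return m.copy()
    labels, n = ndimage.label(m, structure=_CONN8)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component.

    Size ties are broken toward the component whose first pixel in
    row-major order comes first.  An empty mask stays empty.
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(m, structure=_CONN8)
    if n == 0:
        return np.zeros_like(m)
    if n == 1:
        return m.copy()
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if candidates.size > 1:
        flat = labels.ravel()
        first_idx = {lab: np.argmax(flat == lab) for lab in candidates}
        chosen = min(candidates, key=lambda lab: first_idx[lab])
    else:
        chosen = candidates[0]
    return labels == chosen
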