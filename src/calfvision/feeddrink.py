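"""Front-view feeding and drinking detection in basin regions of interest.

Two fixed ROIs are cut from the front camera: the feeding basin (default
91x91 px) and the drinking basin (default 251x192 px).  Inside each ROI the
calf's head is segmented by background subtraction (median filter, Otsu,
4x4 closing, largest component, hole filling).  Feeding fires when the head
reaches the basin's bottom border (Dt >= Df - 5, Df = 48 in ROI-local rows)
with at least 1950 px of area; drinking fires when the head area exceeds
St = 2900 px (strictly), which separates true drinking from a head merely
poked in or "looking around".  Whenever an ROI contains no head, its current
frame replaces that ROI's background, keeping the reference fresh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import DetectionParams, box_from_mask
from .imaging import (
    close_binary,
    fill_holes,
    largest_component,
    median_filter,
    square_element,
    to_grayscale,
)
from .detection import _subtract_filtered, _threshold_difference  # noqa: F401  (shared guard)

__all__ = [
    "FEEDING",
    "DRINKING",
    "NEITHER",
    "BasinROI",
    "FeedDrinkParams",
    "HeadDetection",
    "detect_head",
    "is_feeding",
    "is_drinking",
    "analyze_front_video",
]

FEEDING = "feed"
DRINKING = "drink"
NEITHER = "neither"


@dataclass(frozen=True)
class BasinROI:
    """A basin region of interest in the front view (1-based origin, inclusive)."""

    kind: str  # "feeding" or "drinking"
    origin: tuple[int, int]  # (row, col) of the ROI's top-left pixel
    size: tuple[int, int]  # (height, width); 91x91 feeding, 251x192 drinking

    def __post_init__(self) -> None:
        if self.kind not in ("feeding", "drinking"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if min(self.origin) < 1 or min(self.size) < 1:
            raise ValueError("origin and size must be positive")

    @property
    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        h, w = self.size
        return slice(r - 1, r - 1 + h), slice(c - 1, c - 1 + w)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        r, c = self.origin
        h, w = self.size
        if r - 1 + h > frame.shape[0] or c - 1 + w > frame.shape[1]:
            raise ValueError(f"ROI {self} exceeds frame shape {frame.shape}")
        return frame[self.slices]


def feeding_roi(origin: tuple[int, int] = (400, 430)) -> BasinROI:
    return BasinROI("feeding", origin, (91, 91))


def drinking_roi(origin: tuple[int, int] = (280, 80)) -> BasinROI:
    return BasinROI("drinking", origin, (251, 192))


@dataclass(frozen=True)
class FeedDrinkParams:
    """Thresholds of the basin rules (all in ROI-local pixels).

    df: bottom border row of the feeding basin mouth.
    border_slack: tolerance on the head's bottom border (feeding fires at
        Dt >= df - border_slack).
    feed_area_min: minimum head area for feeding (inclusive).
    st: drinking area threshold (strictly greater-than).
    """

    df: int = 48
    feed_area_min: int = 1950
    st: int = 2900
    border_slack: int = 5

    def __post_init__(self) -> None:
        if min(self.df, self.feed_area_min, self.st, self.border_slack) <= 0:
            raise ValueError("all parameters must be positive")


@dataclass(frozen=True)
class HeadDetection:
    """Segmented head region: pixel count S and bottom border Dt (ROI-local, 1-based)."""

    s: int
    dt: Optional[int]

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("S must be >= 0")
        if (self.s > 0) != (self.dt is not None):
            raise ValueError("Dt is defined exactly when S > 0")


def detect_head(
    roi_frame: np.ndarray,
    roi_background: np.ndarray,
    params: DetectionParams | None = None,
) -> HeadDetection:
    """Segment the head inside one ROI by background subtraction.

    Median filter -> |difference| -> Otsu (with the degeneracy guard) ->
    4x4 closing -> largest component -> hole filling.  Returns the
    component's pixel count S and its bottom row Dt.
    """
    params = params or DetectionParams()
    cur = median_filter(to_grayscale(roi_frame), params.median_window)
    ref = median_filter(to_grayscale(roi_background), params.median_window)
    if cur.shape != ref.shape:
        raise ValueError("ROI frame and background dimensions differ")
    diff = np.abs(cur.astype(np.int16) - ref.astype(np.int16)).astype(np.uint8)
    mask = _threshold_difference(diff, params)
    mask = close_binary(mask, square_element(params.closing_size))
    mask = largest_component(mask)
    mask = fill_holes(mask)
    s = int(mask.sum())
    if s == 0:
        return HeadDetection(0, None)
    box = box_from_mask(mask)
    assert box is not None
    return HeadDetection(s, box.dtest)


def is_feeding(det: HeadDetection, params: FeedDrinkParams | None = None) -> bool:
    """Feeding rule: head at the basin bottom (Dt >= Df - slack) with S >= area floor."""
    p = params or FeedDrinkParams()
    if det.s == 0 or det.dt is None:
        return False
    return det.dt >= p.df - p.border_slack and det.s >= p.feed_area_min


def is_drinking(det: HeadDetection, params: FeedDrinkParams | None = None) -> bool:
    """Drinking rule: head area strictly greater than the St threshold."""
    p = params or FeedDrinkParams()
    return det.s > p.st


def analyze_front_video(
    frames: Sequence[np.ndarray],
    rois: Sequence[BasinROI],
    params: FeedDrinkParams | None = None,
    side_gate: Sequence[bool] | None = None,
    detection_params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Per-frame feeding/drinking labels from the front camera.

    ``side_gate`` marks frames where the side view put the calf in Area B;
    ungated frames are labeled ``neither`` without touching the ROI
    backgrounds.  When absent, every frame is analyzed (front-only runs).
    Each ROI keeps its own background, initialized from the first frame
    (assumed head-free) and replaced by the current ROI whenever no head is
    detected.  If the feeding and drinking rules both fire on one frame the
    conflict is resolved as feeding.

    Returns a DataFrame with one row per frame: label plus per-ROI S and Dt.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    p = params or FeedDrinkParams()
    dp = detection_params or DetectionParams()
    if side_gate is not None and len(side_gate) != len(frames):
        raise ValueError("side_gate length must match the frame count")

    backgrounds = {roi.kind: roi.crop(to_grayscale(frames[0])).copy() for roi in rois}
    records = []
    for i, frame in enumerate(frames):
        gray = to_grayscale(frame)
        rec: dict = {"frame": i + 1, "label": NEITHER}
        if side_gate is not None and not side_gate[i]:
            records.append(rec)
            continue
        feeding = drinking = False
        for roi in rois:
            crop = roi.crop(gray)
            det = detect_head(crop, backgrounds[roi.kind], dp)
            rec[f"{roi.kind}_s"] = det.s
            rec[f"{roi.kind}_dt"] = det.dt
            if det.s == 0:
                backgrounds[roi.kind] = crop.copy()
            if roi.kind == "feeding":
                feeding = is_feeding(det, p)
            else:
                drinking = is_drinking(det, p)
        if feeding:
            rec["label"] = FEEDING
            rec["conflict"] = drinking
        elif drinking:
            rec["label"] = DRINKING
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("frame")
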