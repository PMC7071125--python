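"""Calf-target detection: the integrated background model and two baselines.

The core idea: detect the calf by subtracting the current frame from a
*synthetic* background that is rebuilt every frame.  After each detection the
new background copies the previous background inside the detected target box
(where the calf hides the pen) and the current frame everywhere else (so
gradual scene changes are absorbed immediately).  This combines the
strengths of plain background subtraction (sees static animals) and
inter-frame differencing (adapts to the scene) in one update rule.

Coordinates: boxes are 1-based inclusive (row 1 is the top image row), which
keeps the border-clamp arithmetic literal; ``TargetBox.slices`` maps to the
0-based numpy half-open convention.

All frames handed to the model are median-filtered grayscale; the background
state lives in that filtered domain so each frame is filtered exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .imaging import (
    close_binary,
    fill_holes,
    median_filter,
    otsu_threshold,
    remove_small_areas,
    square_element,
    to_grayscale,
)

__all__ = [
    "RawBox",
    "TargetBox",
    "DetectionParams",
    "BackgroundState",
    "box_from_mask",
    "expand_box",
    "subtract_background",
    "synthesize_background",
    "detect_sequence",
    "frame_difference_baseline",
    "static_background_baseline",
]


@dataclass(frozen=True)
class RawBox:
    """Tight borders of a mask's nonzero region, 1-based inclusive."""

    utest: int
    dtest: int
    ltest: int
    rtest: int

    def __post_init__(self) -> None:
        if not (1 <= self.utest <= self.dtest and 1 <= self.ltest <= self.rtest):
            raise ValueError(f"invalid raw box {self}")


@dataclass(frozen=True)
class TargetBox:
    """Search-box borders (top, bottom, left, right), 1-based inclusive."""

    uend: int
    dend: int
    lend: int
    rend: int

    def __post_init__(self) -> None:
        if not (1 <= self.uend <= self.dend and 1 <= self.lend <= self.rend):
            raise ValueError(f"invalid target box {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        """0-based numpy slices covering the box."""
        return slice(self.uend - 1, self.dend), slice(self.lend - 1, self.rend)

    @property
    def width(self) -> int:
        return self.rend - self.lend + 1

    @property
    def height(self) -> int:
        return self.dend - self.uend + 1


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection chain.

    margin: outward expansion of the tight box into the search box (px).
    min_area: post-threshold components smaller than this are dropped (px).
    median_window: square median-filter size applied to every frame.
    closing_size: side of the square closing element.
    min_contrast: Otsu degeneracy guard — minimum separation (gray levels)
        between the foreground and background mean of the |difference| image;
        below it the difference is treated as target-free noise.
    """

    margin: int = 5
    min_area: int = 100
    median_window: int = 3
    closing_size: int = 4
    min_contrast: float = 10.0

    def __post_init__(self) -> None:
        if self.margin < 0 or self.min_area < 0 or self.min_contrast < 0:
            raise ValueError("margin, min_area and min_contrast must be >= 0")


@dataclass
class BackgroundState:
    """Mutable per-sequence state: the current synthetic background.

    ``background`` is stored median-filtered (the whole chain operates on
    filtered frames); build states with :meth:`from_frame`.
    """

    background: np.ndarray
    last_box: Optional[TargetBox] = None
    frame_index: int = 0

    @classmethod
    def from_frame(cls, frame: np.ndarray, params: DetectionParams | None = None) -> "BackgroundState":
        params = params or DetectionParams()
        return cls(background=median_filter(to_grayscale(frame), params.median_window))


def box_from_mask(mask: np.ndarray) -> Optional[RawBox]:
    """Tight 1-based bounding box of a mask's nonzero set; None if empty."""
    m = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(m.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(m.any(axis=0))
    return RawBox(int(rows[0]) + 1, int(rows[-1]) + 1, int(cols[0]) + 1, int(cols[-1]) + 1)


def expand_box(raw: RawBox, height: int = 576, width: int = 704, margin: int = 5) -> TargetBox:
    """Expand a tight box outward by ``margin`` px, clamped to the image border.

    When an expanded border would overflow the image, the image border
    (row/column 1, or height/width) becomes the search-box border.
    """
    if raw.dtest > height or raw.rtest > width:
        raise ValueError(f"{raw} lies outside a {height}x{width} image")
    return TargetBox(
        uend=max(raw.utest - margin, 1),
        dend=min(raw.dtest + margin, height),
        lend=max(raw.ltest - margin, 1),
        rend=min(raw.rtest + margin, width),
    )


def _threshold_difference(diff: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Otsu-segment an absolute-difference image with the degeneracy guard."""
    level, degenerate = otsu_threshold(diff)
    if degenerate:
        # Constant difference: either nothing changed (empty mask) or the
        # whole scene shifted by more than the guard (all foreground —
        # e.g. a global illumination jump against a stale background).
        if level > params.min_contrast:
            return np.ones(diff.shape, dtype=bool)
        return np.zeros(diff.shape, dtype=bool)
    raw = diff > level
    fg = diff[raw]
    bg = diff[~raw]
    if fg.size == 0 or bg.size == 0:
        return np.zeros(diff.shape, dtype=bool)
    if float(fg.mean()) - float(bg.mean()) < params.min_contrast:
        # The two Otsu classes are barely separated: noise, not a target.
        return np.zeros(diff.shape, dtype=bool)
    return raw


def _postprocess(mask: np.ndarray, params: DetectionParams) -> np.ndarray:
    mask = remove_small_areas(mask, params.min_area)
    mask = close_binary(mask, square_element(params.closing_size))
    return fill_holes(mask)


def _subtract_filtered(filtered: np.ndarray, background: np.ndarray, params: DetectionParams) -> np.ndarray:
    if filtered.shape != background.shape:
        raise ValueError(f"frame shape {filtered.shape} != background shape {background.shape}")
    diff = np.abs(filtered.astype(np.int16) - background.astype(np.int16)).astype(np.uint8)
    return _postprocess(_threshold_difference(diff, params), params)


def subtract_background(
    frame: np.ndarray,
    state: BackgroundState,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Foreground mask of ``frame`` against the state's background.

    The frame is converted to grayscale and median-filtered, the absolute
    difference against the (already filtered) background is Otsu-segmented,
    then small areas are removed, the mask is closed with the square element
    and holes are filled.
    """
    params = params or DetectionParams()
    filtered = median_filter(to_grayscale(frame), params.median_window)
    return _subtract_filtered(filtered, state.background, params)


def synthesize_background(frame: np.ndarray, box: TargetBox, state: BackgroundState) -> np.ndarray:
    """Build the next background: previous background inside ``box``, current frame outside.

    ``frame`` should be in the same (filtered grayscale) domain as the state
    background; :func:`detect_sequence` handles that bookkeeping.
    """
    frame = np.asarray(frame)
    if frame.shape != state.background.shape:
        raise ValueError("frame and background dimensions differ")
    if box.dend > frame.shape[0] or box.rend > frame.shape[1]:
        raise ValueError(f"{box} lies outside the frame")
    out = frame.copy()
    out[box.slices] = state.background[box.slices]
    return out


def detect_sequence(
    frames: Sequence[np.ndarray],
    initial_background: np.ndarray | None = None,
    params: DetectionParams | None = None,
) -> list[tuple[Optional[TargetBox], np.ndarray]]:
    """Run the integrated background model over a frame sequence.

    Per frame: subtract the current synthetic background, take the tight box
    of the surviving mask, expand it by the margin, and synthesize the next
    background (previous background inside the box, current frame outside).
    An empty mask yields an absent box and the whole current frame becomes
    the new background.

    If no ``initial_background`` is given the first frame is used, which
    assumes the sequence starts target-free.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    params = params or DetectionParams()
    state = BackgroundState.from_frame(
        frames[0] if initial_background is None else initial_background, params
    )
    height, width = state.background.shape
    results: list[tuple[Optional[TargetBox], np.ndarray]] = []
    for i, frame in enumerate(frames):
        filtered = median_filter(to_grayscale(frame), params.median_window)
        mask = _subtract_filtered(filtered, state.background, params)
        raw = box_from_mask(mask)
        if raw is None:
            box = None
            state.background = filtered
        else:
            box = expand_box(raw, height, width, params.margin)
            state.background = synthesize_background(filtered, box, state)
        state.last_box = box
        state.frame_index = i + 1
        results.append((box, mask))
    return results


def frame_difference_baseline(
    frames: Sequence[np.ndarray],
    params: DetectionParams | None = None,
) -> list[np.ndarray]:
    """Inter-frame difference baseline: segment |frame_i - frame_{i-1}|.

    Strong noise rejection, but blind to static targets — consecutive
    identical frames produce an empty mask.  The first frame has no
    predecessor and yields an empty mask.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("frame differencing needs at least two frames")
    params = params or DetectionParams()
    filtered = [median_filter(to_grayscale(f), params.median_window) for f in frames]
    masks = [np.zeros(filtered[0].shape, dtype=bool)]
    for prev, cur in zip(filtered[:-1], filtered[1:]):
        masks.append(_subtract_filtered(cur, prev, params))
    return masks


def static_background_baseline(
    frames: Sequence[np.ndarray],
    fixed_background: np.ndarray,
    params: DetectionParams | None = None,
) -> list[np.ndarray]:
    """Conventional background subtraction against a never-updated background."""
    params = params or DetectionParams()
    state = BackgroundState.from_frame(fixed_background, params)
    return [subtract_background(f, state, params) for f in frames]
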