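"""Boundary features of the detected target box and their windowed means.

Three features per frame drive the resting-area behavior rules: the right
border column BR, the left border column BL, and their distance BD = BR - BL.
Because the animal moves continuously, each frame is summarized by two
overlapping 10-frame means — a "previous" window [n-5, n+4] and a "next"
window [n, n+9] — whose difference measures displacement around frame n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import TargetBox

__all__ = ["FeatureSeries", "WindowedFeatures", "extract_features", "windowed_means"]


@dataclass
class FeatureSeries:
    """Per-frame boundary features; NaN where the target is absent."""

    br: np.ndarray
    bl: np.ndarray
    bd: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.present)
        if not (len(self.br) == len(self.bl) == len(self.bd) == n):
            raise ValueError("feature arrays must share one length")

    def __len__(self) -> int:
        return len(self.present)


@dataclass(frozen=True)
class WindowedFeatures:
    """Previous/next window means of BR, BD, BL centered at one frame.

    ``defined`` is False when either window sticks out of the series or
    contains an absent frame; the classifier skips such frames.
    """

    prev_br: float
    next_br: float
    prev_bd: float
    next_bd: float
    prev_bl: float
    next_bl: float
    defined: bool


def extract_features(boxes: Sequence[Optional[TargetBox]]) -> FeatureSeries:
    """BR/BL/BD per frame from a list of boxes (None marks an absent target)."""
    n = len(boxes)
    br = np.full(n, np.nan)
    bl = np.full(n, np.nan)
    present = np.zeros(n, dtype=bool)
    for i, box in enumerate(boxes):
        if box is not None:
            br[i] = box.rend
            bl[i] = box.lend
            present[i] = True
    return FeatureSeries(br=br, bl=bl, bd=br - bl, present=present)


def windowed_means(series: FeatureSeries, n: int, window: int = 10) -> WindowedFeatures:
    """Two overlapping window means around 1-based frame index ``n``.

    previous window: frames [n-5, n-5+window-1]; next window: [n, n+window-1].
    With the default window of 10 these are [n-5, n+4] and [n, n+9],
    overlapping by half a window.  Requires n >= 6 and both windows fully
    inside the series with every frame present; otherwise the result is
    flagged undefined.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    undefined = WindowedFeatures(*([np.nan] * 6), defined=False)
    prev_start = n - 6  # 0-based index of frame n-5
    next_start = n - 1  # 0-based index of frame n
    if n < 6 or prev_start < 0 or next_start + window > len(series):
        return undefined
    prev_sl = slice(prev_start, prev_start + window)
    next_sl = slice(next_start, next_start + window)
    if not (series.present[prev_sl].all() and series.present[next_sl].all()):
        return undefined
    return WindowedFeatures(
        prev_br=float(series.br[prev_sl].mean()),
        next_br=float(series.br[next_sl].mean()),
        prev_bd=float(series.bd[prev_sl].mean()),
        next_bd=float(series.bd[next_sl].mean()),
        prev_bl=float(series.bl[prev_sl].mean()),
        next_bl=float(series.bl[next_sl].mean()),
        defined=True,
    )
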