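"""Rule-based classification of resting-area behaviors.

Each eligible frame (target present, right border inside the resting-area
gate zone "Area A", both feature windows defined) is labeled by comparing
the previous/next 10-frame means of the boundary features:

* enter — BR and BD both drop by more than ``move_thresh`` (calf slides left
  into the resting area), the left border barely moves, and BL at the window
  start is below ``bl_gate`` (the calf is already hugging the dark resting
  strip, where its left border pins).
* leave — the mirror image: BR and BD both grow by more than ``move_thresh``.
* still — all three windowed differences stay within ``still_thresh``.
* turn — mixed-sign combinations: the right border holds still while the
  body foreshortens (BD drops, BL rises) or re-extends (BD grows, BL moves),
  again gated on BL at the window start.

When several systems hold at once the precedence is
enter > leave > still > turn: displacement evidence outranks the rest and
the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureSeries, WindowedFeatures, windowed_means

__all__ = [
    "ENTER",
    "LEAVE",
    "STILL",
    "TURN",
    "UNDETERMINED",
    "BEHAVIOR_CLASSES",
    "RuleThresholds",
    "ZoneConfig",
    "BehaviorEvent",
    "classify_frame",
    "classify_frames",
    "classify_sequence",
    "recognition_table",
]

ENTER = "enter"
LEAVE = "leave"
STILL = "still"
TURN = "turn"
UNDETERMINED = "undetermined"
MISSED = "missed"

BEHAVIOR_CLASSES = (ENTER, LEAVE, STILL, TURN)


@dataclass(frozen=True)
class RuleThresholds:
    """Pixel thresholds of the inequality systems.

    move_thresh: windowed-mean displacement that counts as movement (px).
    still_thresh: windowed-mean fluctuation tolerated while stationary (px).
    bl_gate: BL at the window start must be below this for enter/leave/turn
        (the calf is at the resting-area edge) (px).
    bl_change_bound: |windowed BL change| allowed during enter/leave (px).
    window: length of each feature window (frames).
    """

    move_thresh: float = 10.0
    still_thresh: float = 3.0
    bl_gate: float = 30.0
    bl_change_bound: float = 30.0
    window: int = 10

    def __post_init__(self) -> None:
        vals = (self.move_thresh, self.still_thresh, self.bl_gate, self.bl_change_bound, self.window)
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if self.still_thresh >= self.move_thresh:
            raise ValueError("still_thresh must be smaller than move_thresh")


@dataclass(frozen=True)
class ZoneConfig:
    """Column zones of the side view (1-based inclusive intervals).

    area_a gates the resting-area rules on the target's right border;
    area_b, further right, gates the front-camera feeding/drinking analysis.
    """

    area_a: tuple[int, int] = (1, 190)
    area_b: tuple[int, int] = (520, 704)
    width: int = 704

    def __post_init__(self) -> None:
        for lo, hi in (self.area_a, self.area_b):
            if not (1 <= lo <= hi <= self.width):
                raise ValueError("zone intervals must lie within [1, width]")
        if self.area_a[1] >= self.area_b[0]:
            raise ValueError("area_a must lie left of area_b")

    def in_area_a(self, br: float) -> bool:
        return self.area_a[0] <= br <= self.area_a[1]

    def in_area_b(self, br: float) -> bool:
        return self.area_b[0] <= br <= self.area_b[1]


@dataclass(frozen=True)
class BehaviorEvent:
    """A maximal run of frames sharing one label (1-based, inclusive)."""

    label: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")


def classify_frame(
    wf: WindowedFeatures,
    bl_at_window_start: float,
    thresholds: RuleThresholds | None = None,
) -> str:
    """Label one frame from its windowed features.

    ``bl_at_window_start`` is BL at frame n-5, the first frame of the
    previous window — the gate anchoring enter/leave/turn to the
    resting-area edge.
    """
    if not wf.defined:
        raise ValueError("windowed features are undefined for this frame")
    t = thresholds or RuleThresholds()
    d_br = wf.prev_br - wf.next_br  # positive when BR is decreasing
    d_bd = wf.prev_bd - wf.next_bd
    d_bl = wf.prev_bl - wf.next_bl
    mv, st = t.move_thresh, t.still_thresh
    gate = bl_at_window_start < t.bl_gate

    enter = d_br > mv and d_bd > mv and abs(d_bl) < t.bl_change_bound and gate
    if enter:
        return ENTER
    leave = -d_br > mv and -d_bd > mv and abs(d_bl) < t.bl_change_bound and gate
    if leave:
        return LEAVE
    still = abs(d_br) < st and abs(d_bd) < st and abs(d_bl) < st
    if still:
        return STILL
    turn_a = (abs(d_br) < st and d_bd > mv and -d_bl > mv) or (
        -d_br > mv and -d_bd > mv and abs(d_bl) < st
    )
    turn_b = (d_br > mv and d_bd > mv and abs(d_bl) < st) or (
        abs(d_br) < st and -d_bd > mv and abs(d_bl) > st
    )
    if (turn_a or turn_b) and gate:
        return TURN
    return UNDETERMINED


def classify_frames(
    series: FeatureSeries,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> list[str]:
    """Per-frame labels for a whole feature series.

    Frames whose raw right border is outside Area A, or whose windows are
    incomplete, are labeled undetermined.
    """
    zones = zones or ZoneConfig()
    thresholds = thresholds or RuleThresholds()
    labels: list[str] = []
    for i in range(len(series)):
        n = i + 1  # 1-based frame index
        if not series.present[i] or not zones.in_area_a(series.br[i]):
            labels.append(UNDETERMINED)
            continue
        wf = windowed_means(series, n, thresholds.window)
        if not wf.defined:
            labels.append(UNDETERMINED)
            continue
        labels.append(classify_frame(wf, float(series.bl[n - 6]), thresholds))
    return labels


def merge_labels(labels: Sequence[str]) -> list[BehaviorEvent]:
    """Merge runs of identical consecutive frame labels into events."""
    events: list[BehaviorEvent] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            events.append(BehaviorEvent(labels[start], start + 1, i))
            start = i
    return events


def classify_sequence(
    series: FeatureSeries,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> list[BehaviorEvent]:
    """Classify every frame and merge equal-label runs into events."""
    return merge_labels(classify_frames(series, zones, thresholds))


def recognition_table(
    predicted: Sequence[str],
    truth: Sequence[str],
    classes: Sequence[str] = BEHAVIOR_CLASSES,
) -> pd.DataFrame:
    """Frame-ratio confusion table in percent.

    One row per true behavior class present in ``truth``; columns are the
    behavior classes plus a ``missed`` column collecting frames whose
    prediction is undetermined (or any label outside ``classes``).  Each row
    sums to 100.  Truth frames labeled outside ``classes`` (e.g. "none"
    filler between scripted behaviors) are excluded.
    """
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    classes = list(classes)
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    rows = [c for c in classes if (true == c).any()]
    cols = classes + [MISSED]
    table = pd.DataFrame(0.0, index=rows, columns=cols)
    for c in rows:
        sel = pred[true == c]
        total = len(sel)
        for label in sel:
            col = label if label in classes else MISSED
            table.loc[c, col] += 1
        table.loc[c] *= 100.0 / total
    table.index.name = "true_behavior"
    return table
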