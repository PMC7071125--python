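"""Synthetic pen scenes with scripted calf behaviors and exact ground truth.

The generator emulates exactly the statistical structure the detector
assumes: a static background (optionally with a dark vertical strip on the
left standing in for the resting area), a single moving two-tone target, and
additive per-pixel Gaussian sensor noise.  Every rendered sequence carries a
per-frame ground-truth label, binary mask, and tight bounding box, so the
whole detection/classification chain can be scored frame by frame without
any farm footage.

Sprite motion is translation with optional horizontal foreshortening (the
visible body width scales as the animal rotates toward or away from the
camera axis) and an optional mirror flip.  Foreshortening is what drives the
turning signature — a fixed right border with a changing body width — which
rigid translation alone cannot produce.

The ``make_*_script`` builders construct trajectories whose *noiseless true
boxes* satisfy the corresponding behavior rule system, and label exactly the
frames on which it holds (running the classifier on the true boxes); frames
in lead-ins or transitions keep their honest label (e.g. ``still``) or
``none``.  A script whose parameters cannot satisfy the rules (e.g. a
per-window displacement below the movement threshold) is rejected outright.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .detection import TargetBox, box_from_mask
from .features import extract_features
from .rules import (
    ENTER,
    LEAVE,
    STILL,
    TURN,
    UNDETERMINED,
    RuleThresholds,
    ZoneConfig,
    classify_frames,
)
from .feeddrink import (
    BasinROI,
    FeedDrinkParams,
    HeadDetection,
    drinking_roi,
    feeding_roi,
    is_drinking,
    is_feeding,
)

__all__ = [
    "NONE_LABEL",
    "CalfSprite",
    "SpritePlacement",
    "BehaviorSegment",
    "Background",
    "SceneScript",
    "GroundTruth",
    "default_calf_sprite",
    "render_scene",
    "true_boxes",
    "make_still_script",
    "make_entering_script",
    "make_leaving_script",
    "make_turning_script",
    "make_feeding_script",
    "make_drinking_script",
    "script_to_dict",
    "script_from_dict",
    "save_script",
    "load_script",
    "frames_checksum",
]

NONE_LABEL = "none"


# ---------------------------------------------------------------------------
# domain types


def _holstein_pattern(height: int, width: int) -> np.ndarray:
    """Dark-patch pattern: interior ellipses on a light base.

    The patches stay clear of the body outline so the outline is always the
    light tone — over the dark resting strip the silhouette border keeps its
    contrast and only interior pixels can be lost (and are recovered by hole
    filling).
    """
    pat = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    for cy, cx, ry, rx in ((0.35, 0.30, 0.18, 0.14), (0.62, 0.65, 0.20, 0.16), (0.30, 0.78, 0.12, 0.09)):
        pat |= ((yy - cy * height) / (ry * height)) ** 2 + ((xx - cx * width) / (rx * width)) ** 2 <= 1.0
    mh, mw = max(1, height // 12), max(1, width // 12)
    interior = np.zeros((height, width), dtype=bool)
    interior[mh : height - mh, mw : width - mw] = True
    return pat & interior


@dataclass(frozen=True)
class CalfSprite:
    """A two-tone (black-and-white coat) rectangular target.

    ``tone_pattern`` marks the dark coat regions (True) against the light
    base; its shape must equal ``body_size``.
    """

    body_size: tuple[int, int]  # (height, width) in px
    tone_pattern: np.ndarray
    dark_tone: int = 20
    light_tone: int = 200
    pattern_name: str = "custom"

    def __post_init__(self) -> None:
        pat = np.asarray(self.tone_pattern, dtype=bool)
        if pat.shape != tuple(self.body_size):
            raise ValueError("tone_pattern dimensions must equal body_size")
        object.__setattr__(self, "tone_pattern", pat)
        for tone in (self.dark_tone, self.light_tone):
            if not 0 <= tone <= 255:
                raise ValueError("tones must lie in [0, 255]")

    def tones(self, width_scale: float = 1.0, mirrored: bool = False) -> np.ndarray:
        """8-bit tone patch at the given horizontal scale (nearest-neighbor)."""
        h, w = self.body_size
        we = max(1, int(round(w * width_scale)))
        cols = np.minimum((np.arange(we) * (w / we)).astype(int), w - 1)
        pat = self.tone_pattern[:, cols]
        if mirrored:
            pat = pat[:, ::-1]
        return np.where(pat, np.uint8(self.dark_tone), np.uint8(self.light_tone))


def default_calf_sprite(
    height: int = 120,
    width: int = 160,
    dark_tone: int = 20,
    light_tone: int = 200,
    pattern: str = "holstein",
) -> CalfSprite:
    """Standard synthetic calf: light base with interior dark patches."""
    if pattern == "holstein":
        pat = _holstein_pattern(height, width)
    elif pattern == "solid":
        pat = np.ones((height, width), dtype=bool)
    else:
        raise ValueError(f"unknown pattern recipe {pattern!r}")
    return CalfSprite((height, width), pat, dark_tone, light_tone, pattern_name=pattern)


@dataclass(frozen=True)
class SpritePlacement:
    """Sprite pose on one frame: 1-based top-left anchor of the scaled sprite.

    The anchor may fall outside the frame; the rendered sprite is clipped to
    the frame and the ground truth follows the clipped footprint.
    """

    row: int
    col: int
    width_scale: float = 1.0
    mirrored: bool = False
    visible: bool = True


@dataclass(frozen=True)
class BehaviorSegment:
    """A labeled frame interval with one placement per frame (1-based, inclusive)."""

    label: str
    start_frame: int
    end_frame: int
    trajectory: tuple[SpritePlacement, ...]

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")
        if len(self.trajectory) != self.end_frame - self.start_frame + 1:
            raise ValueError("trajectory length must equal the segment length")
        object.__setattr__(self, "trajectory", tuple(self.trajectory))


@dataclass(frozen=True)
class Background:
    """Flat pen background with an optional dark resting strip at the left."""

    level: int = 120
    strip_width: int = 40
    strip_tone: int = 60

    def render(self, frame_size: tuple[int, int]) -> np.ndarray:
        h, w = frame_size
        arr = np.full((h, w), self.level, dtype=np.uint8)
        if self.strip_width > 0:
            arr[:, : min(self.strip_width, w)] = self.strip_tone
        return arr


@dataclass(frozen=True)
class SceneScript:
    """Declarative description of one synthetic sequence."""

    n_frames: int
    segments: tuple[BehaviorSegment, ...]
    sprite: CalfSprite = field(default_factory=default_calf_sprite)
    background: Background = Background()
    frame_size: tuple[int, int] = (576, 704)
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.frame_size) < 1:
            raise ValueError("frame_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        h, w = self.sprite.body_size
        if h >= self.frame_size[0] or w >= self.frame_size[1]:
            raise ValueError("sprite body must be smaller than the frame")
        segs = tuple(sorted(self.segments, key=lambda s: s.start_frame))
        expected = 1
        for seg in segs:
            if seg.start_frame != expected:
                raise ValueError("segments must tile [1, n_frames] without gaps or overlap")
            expected = seg.end_frame + 1
        if expected != self.n_frames + 1:
            raise ValueError("segments must cover exactly [1, n_frames]")
        object.__setattr__(self, "segments", segs)

    def placements(self) -> list[SpritePlacement]:
        out: list[SpritePlacement] = []
        for seg in self.segments:
            out.extend(seg.trajectory)
        return out

    def labels(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            out.extend([seg.label] * (seg.end_frame - seg.start_frame + 1))
        return out


@dataclass
class GroundTruth:
    """Per-frame truth: behavior label, binary mask, tight bounding box."""

    labels: list[str]
    masks: np.ndarray  # (n, H, W) bool
    boxes: list[Optional[TargetBox]]


# ---------------------------------------------------------------------------
# rendering


def _footprint(
    placement: SpritePlacement, body: tuple[int, int], frame_size: tuple[int, int]
) -> Optional[tuple[slice, slice, slice, slice]]:
    """Frame and patch slices of the clipped sprite; None if fully outside."""
    h = body[0]
    we = max(1, int(round(body[1] * placement.width_scale)))
    H, W = frame_size
    r0, c0 = placement.row - 1, placement.col - 1  # 0-based top-left
    fr0, fr1 = max(r0, 0), min(r0 + h, H)
    fc0, fc1 = max(c0, 0), min(c0 + we, W)
    if fr0 >= fr1 or fc0 >= fc1:
        return None
    return (
        slice(fr0, fr1),
        slice(fc0, fc1),
        slice(fr0 - r0, fr1 - r0),
        slice(fc0 - c0, fc1 - c0),
    )


def true_boxes(script: SceneScript) -> list[Optional[TargetBox]]:
    """Noiseless tight bounding boxes implied by the script's geometry."""
    boxes: list[Optional[TargetBox]] = []
    for pl in script.placements():
        if not pl.visible:
            boxes.append(None)
            continue
        fp = _footprint(pl, script.sprite.body_size, script.frame_size)
        if fp is None:
            boxes.append(None)
        else:
            rs, cs = fp[0], fp[1]
            boxes.append(TargetBox(rs.start + 1, rs.stop, cs.start + 1, cs.stop))
    return boxes


def render_scene(script: SceneScript) -> tuple[np.ndarray, GroundTruth]:
    """Render a script into frames plus exact ground truth.

    Each frame is background + sprite at the scripted pose + clipped
    i.i.d. Gaussian noise.  Identical script and seed reproduce bit-identical
    output.
    """
    H, W = script.frame_size
    bg = script.background.render(script.frame_size)
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    frames = np.empty((n, H, W), dtype=np.uint8)
    masks = np.zeros((n, H, W), dtype=bool)
    boxes: list[Optional[TargetBox]] = []
    for i, pl in enumerate(script.placements()):
        canvas = bg.copy()
        box: Optional[TargetBox] = None
        if pl.visible:
            fp = _footprint(pl, script.sprite.body_size, script.frame_size)
            if fp is not None:
                rs, cs, prs, pcs = fp
                tones = script.sprite.tones(pl.width_scale, pl.mirrored)
                canvas[rs, cs] = tones[prs, pcs]
                masks[i, rs, cs] = True
                box = TargetBox(rs.start + 1, rs.stop, cs.start + 1, cs.stop)
        if script.noise_sigma > 0:
            noisy = canvas.astype(np.float64) + rng.normal(0.0, script.noise_sigma, (H, W))
            canvas = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
        frames[i] = canvas
        boxes.append(box)
    return frames, GroundTruth(labels=script.labels(), masks=masks, boxes=boxes)


def frames_checksum(frames: np.ndarray) -> str:
    """SHA-256 of the raw frame bytes (for determinism checks)."""
    return hashlib.sha256(np.ascontiguousarray(frames).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# script builders


def _segments_from_labels(
    labels: Sequence[str], placements: Sequence[SpritePlacement]
) -> tuple[BehaviorSegment, ...]:
    segs: list[BehaviorSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append(BehaviorSegment(labels[start], start + 1, i, tuple(placements[start:i])))
            start = i
    return tuple(segs)


def _build_side_script(
    placements: list[SpritePlacement],
    target_label: str,
    min_target_frames: int,
    *,
    sprite: CalfSprite,
    background: Background,
    frame_size: tuple[int, int],
    noise_sigma: float,
    seed: int,
    zones: ZoneConfig,
    thresholds: RuleThresholds,
) -> SceneScript:
    """Assemble a side-view script and label frames by the rules on true boxes."""
    provisional = SceneScript(
        n_frames=len(placements),
        segments=(BehaviorSegment(NONE_LABEL, 1, len(placements), tuple(placements)),),
        sprite=sprite,
        background=background,
        frame_size=frame_size,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    series = extract_features(true_boxes(provisional))
    labels = [NONE_LABEL if lab == UNDETERMINED else lab for lab in classify_frames(series, zones, thresholds)]
    n_target = labels.count(target_label)
    if n_target < min_target_frames:
        raise ValueError(
            f"trajectory yields only {n_target} frames satisfying the {target_label!r} "
            f"rule system on the true boxes (need >= {min_target_frames}); "
            "increase the per-frame displacement or the segment length"
        )
    return replace(provisional, segments=_segments_from_labels(labels, placements))


def _side_defaults(sprite, background, zones, thresholds):
    return (
        sprite or default_calf_sprite(),
        background or Background(),
        zones or ZoneConfig(),
        thresholds or RuleThresholds(),
    )


def make_still_script(
    n_frames: int = 120,
    row: int = 230,
    col: int = 20,
    *,
    sprite: CalfSprite | None = None,
    background: Background | None = None,
    frame_size: tuple[int, int] = (576, 704),
    noise_sigma: float = 5.0,
    seed: int = 0,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> SceneScript:
    """A calf standing motionless with its right border inside Area A."""
    sprite, background, zones, thresholds = _side_defaults(sprite, background, zones, thresholds)
    placements = [SpritePlacement(row, col)] * n_frames
    return _build_side_script(
        placements, STILL, 15,
        sprite=sprite, background=background, frame_size=frame_size,
        noise_sigma=noise_sigma, seed=seed, zones=zones, thresholds=thresholds,
    )


def _require_speed(speed: int, thresholds: RuleThresholds, what: str) -> None:
    # The two windows are offset by half a window (5 frames), so a linear
    # border moving at `speed` px/frame separates the window means by
    # 5*speed px; the rule needs that to exceed move_thresh strictly.
    if 5 * speed <= thresholds.move_thresh:
        raise ValueError(
            f"{what}: per-window displacement 5*speed = {5 * speed} px does not exceed "
            f"the movement threshold ({thresholds.move_thresh} px); the rule system "
            "cannot hold on the true boxes"
        )


def make_entering_script(
    speed: int = 3,
    row: int = 230,
    start_col: int = 10,
    lead_frames: int = 12,
    tail_frames: int = 15,
    *,
    sprite: CalfSprite | None = None,
    background: Background | None = None,
    frame_size: tuple[int, int] = (576, 704),
    noise_sigma: float = 5.0,
    seed: int = 0,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> SceneScript:
    """The calf walks left into the resting area (off the left frame edge).

    As the body crosses the frame border the true box's left border pins at
    column 1 while BR and BD shrink — the entering signature.  The walk
    stops with a sliver still visible so the target never vanishes.
    """
    sprite, background, zones, thresholds = _side_defaults(sprite, background, zones, thresholds)
    _require_speed(speed, thresholds, "entering script")
    body_w = sprite.body_size[1]
    end_col = -(body_w - 40)  # leave ~40 px visible at the end
    cols = list(range(start_col, end_col - 1, -speed))
    placements = (
        [SpritePlacement(row, start_col)] * lead_frames
        + [SpritePlacement(row, c) for c in cols]
        + [SpritePlacement(row, cols[-1])] * tail_frames
    )
    return _build_side_script(
        placements, ENTER, 15,
        sprite=sprite, background=background, frame_size=frame_size,
        noise_sigma=noise_sigma, seed=seed, zones=zones, thresholds=thresholds,
    )


def make_leaving_script(
    speed: int = 3,
    row: int = 230,
    end_col: int = 10,
    lead_frames: int = 12,
    tail_frames: int = 15,
    *,
    sprite: CalfSprite | None = None,
    background: Background | None = None,
    frame_size: tuple[int, int] = (576, 704),
    noise_sigma: float = 5.0,
    seed: int = 0,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> SceneScript:
    """The calf walks right out of the resting area: BR and BD grow, BL pinned."""
    sprite, background, zones, thresholds = _side_defaults(sprite, background, zones, thresholds)
    _require_speed(speed, thresholds, "leaving script")
    body_w = sprite.body_size[1]
    start_col = -(body_w - 40)
    cols = list(range(start_col, end_col + 1, speed))
    placements = (
        [SpritePlacement(row, start_col)] * lead_frames
        + [SpritePlacement(row, c) for c in cols]
        + [SpritePlacement(row, cols[-1])] * tail_frames
    )
    return _build_side_script(
        placements, LEAVE, 15,
        sprite=sprite, background=background, frame_size=frame_size,
        noise_sigma=noise_sigma, seed=seed, zones=zones, thresholds=thresholds,
    )


def make_turning_script(
    speed: int = 3,
    row: int = 230,
    right_col: int = 150,
    min_width: int = 100,
    hold_frames: int = 12,
    mid_hold_frames: int = 8,
    *,
    sprite: CalfSprite | None = None,
    background: Background | None = None,
    frame_size: tuple[int, int] = (576, 704),
    noise_sigma: float = 5.0,
    seed: int = 0,
    zones: ZoneConfig | None = None,
    thresholds: RuleThresholds | None = None,
) -> SceneScript:
    """The calf pivots in place at the resting-area edge.

    The right border stays pinned at ``right_col`` while the visible body
    width foreshortens down to ``min_width`` and re-extends — BD shrinks then
    grows with BL countering, the turning signature.
    """
    sprite, background, zones, thresholds = _side_defaults(sprite, background, zones, thresholds)
    _require_speed(speed, thresholds, "turning script")
    body_w = sprite.body_size[1]
    if not 1 <= min_width < body_w:
        raise ValueError("min_width must lie in [1, body width)")
    widths = (
        [body_w] * hold_frames
        + list(range(body_w, min_width - 1, -speed))
        + [min_width] * mid_hold_frames
        + list(range(min_width, body_w + 1, speed))
        + [body_w] * hold_frames
    )
    placements = [
        SpritePlacement(row, right_col - w + 1, width_scale=w / body_w) for w in widths
    ]
    return _build_side_script(
        placements, TURN, 8,
        sprite=sprite, background=background, frame_size=frame_size,
        noise_sigma=noise_sigma, seed=seed, zones=zones, thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# front-view (feeding / drinking) builders


def _head_sprite(height: int, width: int, tone: int = 40) -> CalfSprite:
    return CalfSprite((height, width), np.ones((height, width), dtype=bool), dark_tone=tone,
                      light_tone=tone, pattern_name="solid")


def make_feeding_script(
    head_size: tuple[int, int] = (44, 50),
    bottom_row: int = 48,
    lead_frames: int = 15,
    feed_frames: int = 50,
    tail_frames: int = 15,
    *,
    roi: BasinROI | None = None,
    params: FeedDrinkParams | None = None,
    frame_size: tuple[int, int] = (576, 704),
    background_level: int = 150,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> tuple[SceneScript, list[BasinROI]]:
    """Front-view script: the head dips to the feeding-basin bottom and feeds.

    The head blob's area (head_size product) and ROI-local bottom border are
    checked against the feeding rule; parameters that cannot satisfy it are
    rejected.  Returns the script plus both basin ROIs (the drinking ROI
    stays empty).
    """
    roi = roi or feeding_roi()
    p = params or FeedDrinkParams()
    h, w = head_size
    if bottom_row > roi.size[0]:
        raise ValueError("bottom_row must lie inside the ROI")
    det = HeadDetection(h * w, bottom_row)
    if not is_feeding(det, p):
        raise ValueError(
            f"head of {h * w} px with bottom border {bottom_row} cannot satisfy the "
            f"feeding rule (needs area >= {p.feed_area_min} and Dt >= {p.df - p.border_slack})"
        )
    row = roi.origin[0] + bottom_row - h  # global 1-based top row
    col = roi.origin[1] + max(1, (roi.size[1] - w) // 2) - 1
    sprite = _head_sprite(h, w)
    n = lead_frames + feed_frames + tail_frames
    placements = (
        [SpritePlacement(row, col, visible=False)] * lead_frames
        + [SpritePlacement(row, col)] * feed_frames
        + [SpritePlacement(row, col, visible=False)] * tail_frames
    )
    labels = [NONE_LABEL] * lead_frames + ["feed"] * feed_frames + [NONE_LABEL] * tail_frames
    script = SceneScript(
        n_frames=n,
        segments=_segments_from_labels(labels, placements),
        sprite=sprite,
        background=Background(level=background_level, strip_width=0),
        frame_size=frame_size,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return script, [roi, drinking_roi()]


def make_drinking_script(
    head_size: tuple[int, int] = (60, 60),
    look_width_scale: float = 1 / 3,
    lead_frames: int = 15,
    look_frames: int = 25,
    drink_frames: int = 45,
    tail_frames: int = 15,
    *,
    roi: BasinROI | None = None,
    params: FeedDrinkParams | None = None,
    frame_size: tuple[int, int] = (576, 704),
    background_level: int = 150,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> tuple[SceneScript, list[BasinROI]]:
    """Front-view script: looking around (small head area), then drinking.

    The full head blob must exceed the drinking area threshold St; the
    foreshortened "looking" blob must stay below it.
    """
    roi = roi or drinking_roi()
    p = params or FeedDrinkParams()
    h, w = head_size
    look_w = max(1, int(round(w * look_width_scale)))
    if not is_drinking(HeadDetection(h * w, h), p):
        raise ValueError(f"head area {h * w} px does not exceed the drinking threshold St = {p.st}")
    if is_drinking(HeadDetection(h * look_w, h), p):
        raise ValueError("the looking pose already exceeds the drinking threshold; shrink look_width_scale")
    row = roi.origin[0] + max(1, (roi.size[0] - h) // 2) - 1
    col = roi.origin[1] + max(1, (roi.size[1] - w) // 2) - 1
    sprite = _head_sprite(h, w)
    n = lead_frames + look_frames + drink_frames + tail_frames
    placements = (
        [SpritePlacement(row, col, visible=False)] * lead_frames
        + [SpritePlacement(row, col, width_scale=look_width_scale)] * look_frames
        + [SpritePlacement(row, col)] * drink_frames
        + [SpritePlacement(row, col, visible=False)] * tail_frames
    )
    labels = (
        [NONE_LABEL] * lead_frames
        + [NONE_LABEL] * look_frames
        + ["drink"] * drink_frames
        + [NONE_LABEL] * tail_frames
    )
    script = SceneScript(
        n_frames=n,
        segments=_segments_from_labels(labels, placements),
        sprite=sprite,
        background=Background(level=background_level, strip_width=0),
        frame_size=frame_size,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return script, [feeding_roi(), roi]


# ---------------------------------------------------------------------------
# serialization (documented YAML schema)


def script_to_dict(script: SceneScript) -> dict:
    """Plain-python representation of a script.

    Schema: frame_size [H, W]; n_frames; noise_sigma; seed;
    background {level, strip_width, strip_tone};
    sprite {height, width, dark_tone, light_tone, pattern};
    segments [{label, start, end, trajectory [[row, col, width_scale,
    mirrored, visible], ...]}].  Only named pattern recipes round-trip.
    """
    if script.sprite.pattern_name == "custom":
        raise ValueError("only named sprite pattern recipes can be serialized")
    return {
        "frame_size": list(script.frame_size),
        "n_frames": script.n_frames,
        "noise_sigma": float(script.noise_sigma),
        "seed": int(script.seed),
        "background": {
            "level": script.background.level,
            "strip_width": script.background.strip_width,
            "strip_tone": script.background.strip_tone,
        },
        "sprite": {
            "height": script.sprite.body_size[0],
            "width": script.sprite.body_size[1],
            "dark_tone": script.sprite.dark_tone,
            "light_tone": script.sprite.light_tone,
            "pattern": script.sprite.pattern_name,
        },
        "segments": [
            {
                "label": seg.label,
                "start": seg.start_frame,
                "end": seg.end_frame,
                "trajectory": [
                    [pl.row, pl.col, float(pl.width_scale), bool(pl.mirrored), bool(pl.visible)]
                    for pl in seg.trajectory
                ],
            }
            for seg in script.segments
        ],
    }


def script_from_dict(data: dict) -> SceneScript:
    sp = data["sprite"]
    sprite = default_calf_sprite(
        sp["height"], sp["width"], sp["dark_tone"], sp["light_tone"], sp["pattern"]
    )
    bg = data["background"]
    segments = tuple(
        BehaviorSegment(
            seg["label"],
            seg["start"],
            seg["end"],
            tuple(SpritePlacement(r, c, ws, mi, vi) for r, c, ws, mi, vi in seg["trajectory"]),
        )
        for seg in data["segments"]
    )
    return SceneScript(
        n_frames=data["n_frames"],
        segments=segments,
        sprite=sprite,
        background=Background(bg["level"], bg["strip_width"], bg["strip_tone"]),
        frame_size=tuple(data["frame_size"]),
        noise_sigma=data["noise_sigma"],
        seed=data["seed"],
    )


def save_script(script: SceneScript, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(script_to_dict(script), fh, sort_keys=False)


def load_script(path) -> SceneScript:
    with open(path) as fh:
        return script_from_dict(yaml.safe_load(fh))
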