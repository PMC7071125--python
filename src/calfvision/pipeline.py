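"""End-to-end orchestration: configuration, the full side-view chain, reports.

``run_pipeline`` composes detection -> boundary features -> behavior rules on
a side-view source (a synthetic scene script or a frame array), optionally
scores the per-frame labels against ground truth into the frame-ratio
recognition table, and packages everything with provenance hashes so that
identical input + configuration + seed always produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams, TargetBox, detect_sequence
from .features import extract_features
from .feeddrink import FeedDrinkParams
from .io import boxes_to_table, truth_labels_table
from .rules import (
    BEHAVIOR_CLASSES,
    BehaviorEvent,
    RuleThresholds,
    ZoneConfig,
    classify_frames,
    merge_labels,
    recognition_table,
)
from .synthetic import GroundTruth, SceneScript, render_scene

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the chain in one serializable object."""

    frame_height: int = 576
    frame_width: int = 704
    fps: float = 25.0  # metadata only; the rules count frames, not seconds
    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    feed_drink: FeedDrinkParams = field(default_factory=FeedDrinkParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "detection" in data:
            data["detection"] = DetectionParams(**data["detection"])
        if "thresholds" in data:
            data["thresholds"] = RuleThresholds(**data["thresholds"])
        if "zones" in data:
            z = dict(data["zones"])
            z["area_a"] = tuple(z["area_a"])
            z["area_b"] = tuple(z["area_b"])
            data["zones"] = ZoneConfig(**z)
        if "feed_drink" in data:
            data["feed_drink"] = FeedDrinkParams(**data["feed_drink"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples/numpy scalars into YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunReport:
    """Everything one run produces.

    table: the frame-ratio recognition table (None without ground truth);
    labels: the per-frame predicted labels;
    events: merged label runs;
    boxes: per-frame detected search boxes;
    provenance: config hash, input hash and package version.
    """

    labels: list[str]
    events: list[BehaviorEvent]
    boxes: list[Optional[TargetBox]]
    table: Optional[pd.DataFrame]
    provenance: dict


def _sha(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(
    source: Union[SceneScript, np.ndarray, Sequence[np.ndarray]],
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
    initial_background: np.ndarray | None = None,
) -> RunReport:
    """Run detection, feature extraction and behavior rules on a side view.

    A :class:`SceneScript` source is rendered first (its clean background
    becomes the initial background and its ground truth is scored
    automatically).  For frame-array sources pass ``initial_background`` (or
    the first frame is assumed target-free) and, optionally, a ground truth.
    """
    config = config or PipelineConfig()
    if isinstance(source, SceneScript):
        frames, rendered_truth = render_scene(source)
        truth = truth or rendered_truth
        if initial_background is None:
            initial_background = source.background.render(source.frame_size)
    else:
        frames = np.asarray(source)
    if frames.ndim not in (3, 4):
        raise ValueError("source frames must be an (n, H, W[, 3]) array")
    if frames.shape[1] != config.frame_height or frames.shape[2] != config.frame_width:
        raise ValueError(
            f"frames are {frames.shape[1]}x{frames.shape[2]} but the config expects "
            f"{config.frame_height}x{config.frame_width}"
        )
    results = detect_sequence(frames, initial_background, config.detection)
    boxes = [box for box, _ in results]
    series = extract_features(boxes)
    labels = classify_frames(series, config.zones, config.thresholds)
    events = merge_labels(labels)
    table = None
    if truth is not None:
        if len(truth.labels) != len(labels):
            raise ValueError("ground-truth label count does not match the frame count")
        table = recognition_table(labels, truth.labels, BEHAVIOR_CLASSES)
    provenance = {
        "version": __version__,
        "config_sha256": _sha(json.dumps(_plain(config.to_dict()), sort_keys=True).encode()),
        "input_sha256": _sha(np.ascontiguousarray(frames).tobytes()),
        "n_frames": int(frames.shape[0]),
    }
    return RunReport(labels=labels, events=events, boxes=boxes, table=table, provenance=provenance)


def write_report(report: RunReport, outdir) -> dict[str, Path]:
    """Serialize a run deterministically: CSV tables plus a text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["labels"] = outdir / "labels.csv"
    truth_labels_table(report.labels).to_csv(paths["labels"], index=False)

    paths["events"] = outdir / "events.csv"
    pd.DataFrame(
        [{"label": e.label, "start_frame": e.start_frame, "end_frame": e.end_frame} for e in report.events]
    ).to_csv(paths["events"], index=False)

    paths["boxes"] = outdir / "boxes.csv"
    boxes_to_table(report.boxes).to_csv(paths["boxes"], index=False)

    if report.table is not None:
        paths["table"] = outdir / "table.csv"
        report.table.to_csv(paths["table"], float_format="%.6f")

    paths["report"] = outdir / "report.txt"
    lines = [
        "calfvision run report",
        f"version: {report.provenance['version']}",
        f"config sha256: {report.provenance['config_sha256']}",
        f"input sha256: {report.provenance['input_sha256']}",
        f"frames: {report.provenance['n_frames']}",
        "",
        "events:",
    ]
    for e in report.events:
        lines.append(f"  {e.label}: frames {e.start_frame}-{e.end_frame}")
    if report.table is not None:
        lines += ["", "recognition table (% of frames per true behavior):",
                  report.table.to_string(float_format=lambda v: f"{v:.2f}")]
    paths["report"].write_text("\n".join(lines) + "\n")
    return paths
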