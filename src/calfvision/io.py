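"""Reading and writing frame sequences, masks and tables.

Frame sequences are exchanged as directories of numbered 8-bit PNGs
(``frame_000123.png`` or any name whose digits give the index); masks as
0/255 PNGs.  Container formats (AVI/MP4) require an ffmpeg-backed imageio
plugin and raise an informative error when that backend is missing.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import imageio.v2 as iio
import numpy as np
import pandas as pd

from .detection import TargetBox

__all__ = [
    "read_sequence",
    "write_frames",
    "write_masks",
    "boxes_to_frame",
    "boxes_to_table",
    "boxes_from_table",
    "truth_labels_table",
]

_INDEX_RE = re.compile(r"(\d+)")


def _numbered_files(directory: Path) -> list[tuple[int, Path]]:
    pairs = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".png", ".bmp", ".tif", ".tiff"):
            continue
        m = _INDEX_RE.findall(path.stem)
        if not m:
            raise ValueError(f"image file {path.name} carries no frame index")
        pairs.append((int(m[-1]), path))
    pairs.sort()
    return pairs


def read_sequence(path) -> np.ndarray:
    """Load frames from a numbered-image directory (or a video container).

    Frames come back in index order as one array of shape (n, H, W[, 3]).
    A missing index in the numbering, or mixed frame sizes, is rejected.
    """
    path = Path(path)
    if path.is_dir():
        pairs = _numbered_files(path)
        if not pairs:
            raise ValueError(f"no image files found in {path}")
        indices = [i for i, _ in pairs]
        expected = list(range(indices[0], indices[0] + len(indices)))
        if indices != expected:
            missing = sorted(set(expected) - set(indices))
            raise ValueError(f"frame numbering has gaps; missing indices: {missing[:10]}")
        frames = [np.asarray(iio.imread(p)) for _, p in pairs]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame sizes in sequence: {sorted(shapes)}")
        return np.stack(frames)
    try:
        reader = iio.get_reader(path)
        frames = [np.asarray(f) for f in reader]
        reader.close()
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise ValueError(
            f"could not read {path} as a video container (an ffmpeg backend may be "
            "missing); use a directory of numbered PNG frames instead"
        ) from exc
    if not frames:
        raise ValueError(f"no frames decoded from {path}")
    return np.stack(frames)


def write_frames(directory, frames: np.ndarray, prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i + 1:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_masks(directory, masks: Sequence[np.ndarray], prefix: str = "mask") -> list[Path]:
    """Masks as 0/255 grayscale PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(masks):
        p = directory / f"{prefix}_{i + 1:06d}.png"
        iio.imwrite(p, (np.asarray(mask, dtype=bool) * np.uint8(255)))
        paths.append(p)
    return paths


def boxes_to_table(boxes: Sequence[Optional[TargetBox]]) -> pd.DataFrame:
    """Boxes as a table: frame, present, Uend, Dend, Lend, Rend."""
    records = []
    for i, box in enumerate(boxes):
        if box is None:
            records.append({"frame": i + 1, "present": False, "Uend": pd.NA,
                            "Dend": pd.NA, "Lend": pd.NA, "Rend": pd.NA})
        else:
            records.append({"frame": i + 1, "present": True, "Uend": box.uend,
                            "Dend": box.dend, "Lend": box.lend, "Rend": box.rend})
    return pd.DataFrame.from_records(records)


def boxes_from_table(table: pd.DataFrame) -> list[Optional[TargetBox]]:
    boxes: list[Optional[TargetBox]] = []
    for _, row in table.sort_values("frame").iterrows():
        if not bool(row["present"]):
            boxes.append(None)
        else:
            boxes.append(TargetBox(int(row["Uend"]), int(row["Dend"]),
                                   int(row["Lend"]), int(row["Rend"])))
    return boxes


def boxes_to_frame(table_path) -> list[Optional[TargetBox]]:
    return boxes_from_table(pd.read_csv(table_path))


def truth_labels_table(labels: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({"frame": np.arange(1, len(labels) + 1), "label": list(labels)})
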