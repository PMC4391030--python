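"""File I/O for detection runs: images, detection CSVs, truth CSVs, configs."""

from __future__ import annotations

import csv
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .detection import DetectionResult, DetectorConfig

DETECTION_FIELDS = ["frame_id", "status", "x", "y", "a", "b",
                    "circularity", "segment_size", "n_candidates"]

IMAGE_SUFFIXES = {".png", ".bmp", ".pgm"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/BMP/PGM frame; RGB inputs stay 3-channel here
    (the detector converts to luminance itself)."""
    return np.asarray(iio.imread(path))


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok
            for tok in re.split(r"(\d+)", name)]


def list_frames(path: str | Path) -> list[Path]:
    """Image files under a directory (or a single file), natural-sorted."""
    p = Path(path)
    if p.is_file():
        return [p]
    frames = [f for f in p.iterdir()
              if f.is_file() and f.suffix.lower() in IMAGE_SUFFIXES]
    return sorted(frames, key=lambda f: _natural_key(f.name))


def detection_row(frame_id: str, result: DetectionResult | None) -> dict:
    """One detection-CSV row; numeric fields empty unless detected."""
    row = {f: "" for f in DETECTION_FIELDS}
    row["frame_id"] = frame_id
    if result is None:
        row["status"] = "error"
    elif result.detected:
        e = result.ellipse
        row.update(status="detected",
                   x=f"{e.h:.3f}", y=f"{e.k:.3f}",
                   a=f"{e.a:.3f}", b=f"{e.b:.3f}",
                   circularity=f"{e.circularity:.3f}",
                   segment_size=str(e.source_size),
                   n_candidates=str(result.n_candidates))
    else:
        row["status"] = "no_pupil"
    return row


def write_detections_csv(path: str | Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=DETECTION_FIELDS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_detections_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def read_truth_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """frame_id -> (x, y) reference pupil centers."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["frame_id"]] = (float(row["x"]), float(row["y"]))
    return out


def read_annotation_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Two-rater annotation CSV (frame_id, x1, y1, x2, y2) -> mid-points."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["frame_id"]] = ((float(row["x1"]) + float(row["x2"])) / 2.0,
                                    (float(row["y1"]) + float(row["y2"])) / 2.0)
    return out


def read_config_file(path: str | Path) -> DetectorConfig:
    """Flat ``key = value`` config: threshold, min_segment_size."""
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key in ("threshold", "min_segment_size"):
            kwargs[key] = int(val.strip())
    return DetectorConfig(**kwargs)
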