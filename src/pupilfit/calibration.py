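"""Simplified gaze calibration: pupil-center pixels to point of regard.

A viewer fixates 5 marked points on a physical calibration cross (arms of
69 cm, viewed from roughly 80-90 cm).  The pupil-center points recorded at
those fixations, paired with the known target positions in cm on the cross
plane, determine a 6-parameter affine map from eye-camera pixels to scene
centimeters.  Gaze accuracy is then reported as visual angle:
arctan(planar offset / viewing distance), in degrees.  No glint or 3-D eye
model is used — this is deliberately the simple planar mapping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class CalibrationSet:
    """Fixation correspondences plus the physical geometry of the cross."""

    pcps: np.ndarray      # (n, 2) pupil centers, px
    targets: np.ndarray   # (n, 2) target positions on the cross plane, cm
    distance: float = 85.0  # viewing distance, cm (midpoint of 80-90)
    arm_length: float = 69.0  # cross arm length, cm

    def __post_init__(self) -> None:
        p = np.asarray(self.pcps, dtype=np.float64)
        t = np.asarray(self.targets, dtype=np.float64)
        if p.shape != t.shape or p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("pcps and targets must both be (n, 2)")
        if p.shape[0] < 3:
            raise ValueError("need at least 3 correspondences")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        object.__setattr__(self, "pcps", p)
        object.__setattr__(self, "targets", t)


@dataclass(frozen=True)
class PorMapping:
    """Affine map px -> cm: [X, Y] = A @ [x, y] + t (6 coefficients)."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix.tolist(),
                       "offset": self.offset.tolist()}, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PorMapping":
        with open(path) as fh:
            d = json.load(fh)
        return cls(matrix=np.asarray(d["matrix"], dtype=np.float64),
                   offset=np.asarray(d["offset"], dtype=np.float64))


def fit_por_mapping(calset: CalibrationSet) -> PorMapping:
    """Least-squares affine map over the correspondences.

    Minimizes summed squared cm residuals; exact (to rounding) when the
    correspondences are truly affine.  Collinear pupil centers leave the
    map under-determined and raise ValueError.
    """
    p, t = calset.pcps, calset.targets
    design = np.column_stack([p, np.ones(len(p))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("calibration points are collinear; affine map undetermined")
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)  # (3, 2)
    return PorMapping(matrix=coef[:2].T.copy(), offset=coef[2].copy())


def map_pcp(mapping: PorMapping, pcp) -> tuple[float, float]:
    """Affine image of one pupil-center point, in cm on the scene plane."""
    out = mapping.matrix @ np.asarray(pcp, dtype=np.float64) + mapping.offset
    return (float(out[0]), float(out[1]))


def angular_error(por, truth, distance: float) -> float:
    """Visual-angle error in degrees: arctan(planar offset / distance)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    (x1, y1), (x2, y2) = por, truth
    return math.degrees(math.atan(math.hypot(x1 - x2, y1 - y2) / distance))


# --- file format -------------------------------------------------------------

def read_calibration_csv(path: str | Path) -> CalibrationSet:
    """Read a calibration file.

    Format: '#'-prefixed header lines carrying ``key = value`` pairs
    (distance_cm, arm_cm), then a CSV header ``pcp_x,pcp_y,target_X_cm,
    target_Y_cm`` and one row per fixation point.
    """
    meta = {"distance_cm": 85.0, "arm_cm": 69.0}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition("=")
            if _:
                meta[key.strip()] = float(val.strip())
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        rows.append([float(v) for v in line.split(",")])
    if not rows:
        raise ValueError(f"no correspondences in {path}")
    arr = np.asarray(rows, dtype=np.float64)
    return CalibrationSet(pcps=arr[:, :2], targets=arr[:, 2:4],
                          distance=meta["distance_cm"], arm_length=meta["arm_cm"])


def write_calibration_csv(path: str | Path, calset: CalibrationSet) -> None:
    lines = [f"# distance_cm = {calset.distance}",
             f"# arm_cm = {calset.arm_length}",
             "pcp_x,pcp_y,target_X_cm,target_Y_cm"]
    for (px, py), (tx, ty) in zip(calset.pcps, calset.targets):
        lines.append(f"{px},{py},{tx},{ty}")
    Path(path).write_text("\n".join(lines) + "\n")
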