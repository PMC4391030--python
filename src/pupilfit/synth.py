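"""Seeded generator of ground-truthed synthetic eye frames.

Emulates the statistical structure of dark-pupil IR eye imagery at two
levels of difficulty: clean laboratory-style frames (centered pupil,
uniform lighting) and degraded outdoor-style frames (eyelid occlusion
truncating the pupil contour, dark eyelash/corner distractor blobs, a
linear illumination ramp, heavier sensor noise).  Every frame is a pure
function of its :class:`EyeSceneSpec`, including the seed, so datasets are
byte-reproducible and every pipeline stage is testable without any image
download.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass(frozen=True)
class Distractor:
    """A dark non-pupil blob that survives thresholding.

    ``bar`` is an elongated rectangle (an eyelash or shadow streak) given by
    geometry (x, y, width, height); ``corner_patch`` is a quarter-disc of
    radius ``geometry[2]`` anchored at corner (x, y).
    """

    kind: str  # "bar" | "corner_patch"
    geometry: tuple[float, ...]
    intensity: int = 15


@dataclass(frozen=True)
class EyeSceneSpec:
    width: int = 640
    height: int = 480
    pupil_center: tuple[float, float] = (320.0, 240.0)
    pupil_axes: tuple[float, float] = (40.0, 38.0)  # (vertical a, horizontal b), px
    pupil_intensity: int = 10
    iris_radius: float = 110.0
    iris_intensity: int = 90
    sclera_intensity: int = 190
    eyelid_occlusion: float = 0.0  # fraction of pupil height hidden from the top
    distractors: tuple[Distractor, ...] = ()
    gradient_amplitude: float = 0.0  # intensity span of a left-to-right ramp
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eyelid_occlusion <= 0.5):
            raise ValueError("eyelid_occlusion must be in [0, 0.5]")
        x, y = self.pupil_center
        a, b = self.pupil_axes
        if self.eyelid_occlusion == 0.0 and not (
            b <= x <= self.width - 1 - b and a <= y <= self.height - 1 - a
        ):
            raise ValueError("pupil must lie entirely within the image when unoccluded")


@dataclass(frozen=True)
class GroundTruth:
    true_pcp: tuple[float, float]
    true_axes: tuple[float, float]  # (a vertical, b horizontal)
    occluded: bool
    distractor_count: int


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    """Pixels whose centers satisfy ((x-h)/b)^2 + ((y-k)/a)^2 <= 1."""
    h, k = center
    a, b = axes
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xs - h) / b) ** 2 + ((ys - k) / a) ** 2 <= 1.0


def render_eye(spec: EyeSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Paint the scene back-to-front, then apply ramp and clamped noise.

    Order: sclera background, iris disc, pupil ellipse, eyelid occlusion
    band (pupil rows hidden from the top are repainted with iris intensity,
    the way a blink truncates the contour), distractors, illumination ramp,
    Gaussian noise clamped to [0, 255].  Identical specs render
    byte-identical frames.
    """
    shape = (spec.height, spec.width)
    img = np.full(shape, float(spec.sclera_intensity))

    h, k = spec.pupil_center
    a, b = spec.pupil_axes
    img[_ellipse_mask(shape, (h, k), (spec.iris_radius, spec.iris_radius))] = spec.iris_intensity
    pupil = _ellipse_mask(shape, (h, k), (a, b))
    img[pupil] = spec.pupil_intensity

    if spec.eyelid_occlusion > 0:
        lid_y = (k - a) + spec.eyelid_occlusion * 2 * a
        ys = np.arange(spec.height)[:, None]
        img[pupil & (ys < lid_y)] = spec.iris_intensity

    for d in spec.distractors:
        if d.kind == "bar":
            x0, y0, w, hgt = d.geometry
            ys, xs = np.mgrid[0:spec.height, 0:spec.width]
            img[(xs >= x0) & (xs < x0 + w) & (ys >= y0) & (ys < y0 + hgt)] = d.intensity
        elif d.kind == "corner_patch":
            cx, cy, r = d.geometry
            ys, xs = np.mgrid[0:spec.height, 0:spec.width]
            img[(xs - cx) ** 2 + (ys - cy) ** 2 <= r**2] = d.intensity
        else:
            raise ValueError(f"unknown distractor kind {d.kind!r}")

    if spec.gradient_amplitude:
        ramp = np.linspace(-spec.gradient_amplitude / 2,
                           spec.gradient_amplitude / 2, spec.width)
        img = img + ramp[None, :]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        true_pcp=(float(h), float(k)),
        true_axes=(float(a), float(b)),
        occluded=spec.eyelid_occlusion > 0,
        distractor_count=len(spec.distractors),
    )
    return img, truth


# --- dataset sampling --------------------------------------------------------

#: Default sampling ranges, chosen to mirror head-mounted IR eye-camera
#: geometry: semi-axes 25-60 px at 640x480, mild ellipticity, moderate
#: occlusion, sensor noise sigma 8, distractors in half the frames.
DEFAULT_RANGES: dict = {
    "pupil_axis": (25.0, 60.0),
    "axis_ratio": (1.0, 1.25),       # a/b ellipticity
    "center_margin": 80,             # px kept clear of every image edge
    "occlusion": (0.0, 0.3),
    "occlusion_prob": 0.5,
    "distractor_prob": 0.5,
    "gradient": (0.0, 30.0),
    "noise_sigma": (8.0, 8.0),
    "pupil_intensity": (5, 20),
}

#: Outdoor-style stress conditions: heavy noise, deep occlusion, strong ramp.
DEGRADED_RANGES: dict = {
    **DEFAULT_RANGES,
    "occlusion": (0.4, 0.4),
    "occlusion_prob": 1.0,
    "gradient": (60.0, 60.0),
    "noise_sigma": (20.0, 20.0),
}


def sample_spec(rng: np.random.Generator, ranges: dict | None = None,
                width: int = 640, height: int = 480) -> EyeSceneSpec:
    """Draw one scene spec from the given per-field ranges."""
    r = {**DEFAULT_RANGES, **(ranges or {})}
    axis = rng.uniform(*r["pupil_axis"])
    ratio = rng.uniform(*r["axis_ratio"])
    a, b = axis * ratio, axis  # vertical major axis, per the upward-ellipse model
    m = r["center_margin"]
    cx = rng.uniform(m, width - 1 - m)
    cy = rng.uniform(m, height - 1 - m)
    occ = rng.uniform(*r["occlusion"]) if rng.random() < r["occlusion_prob"] else 0.0
    distractors: list[Distractor] = []
    if rng.random() < r["distractor_prob"]:
        # an eyelash-like bar well away from the pupil, aspect ~ 4
        bw, bh = rng.uniform(80, 140), rng.uniform(18, 30)
        bx = rng.uniform(0, width - bw)
        by = 10.0 if cy > height / 2 else height - 10.0 - bh
        distractors.append(Distractor("bar", (bx, by, bw, bh),
                                      intensity=int(rng.integers(5, 25))))
        if rng.random() < 0.3:
            distractors.append(Distractor(
                "corner_patch", (0.0, 0.0, rng.uniform(35, 60)),
                intensity=int(rng.integers(5, 25))))
    lo, hi = r["pupil_intensity"]
    return EyeSceneSpec(
        width=width, height=height,
        pupil_center=(float(cx), float(cy)),
        pupil_axes=(float(a), float(b)),
        pupil_intensity=int(rng.integers(lo, hi + 1)),
        eyelid_occlusion=float(occ),
        distractors=tuple(distractors),
        gradient_amplitude=float(rng.uniform(*r["gradient"])),
        noise_sigma=float(rng.uniform(*r["noise_sigma"])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n: int, ranges: dict | None = None, seed: int = 0,
                     outdir: str | Path | None = None,
                     invocation: str | None = None):
    """Generate ``n`` ground-truthed frames; optionally write them to disk.

    Returns ``(specs, truths, images)``.  With ``outdir`` set, writes
    ``frame_0000.png``..., ``truth.csv`` (frame_id, x, y, a, b, occluded,
    distractor_count) and ``manifest.json`` recording every spec, the seed
    and the CLI invocation so the dataset can be replayed exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = [sample_spec(rng, ranges) for _ in range(n)]
    rendered = [render_eye(s) for s in specs]
    images = [im for im, _ in rendered]
    truths = [t for _, t in rendered]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, truth) in enumerate(zip(images, truths)):
            fid = f"frame_{i:04d}"
            iio.imwrite(outdir / f"{fid}.png", img)
            rows.append({
                "frame_id": fid,
                "x": f"{truth.true_pcp[0]:.3f}", "y": f"{truth.true_pcp[1]:.3f}",
                "a": f"{truth.true_axes[0]:.3f}", "b": f"{truth.true_axes[1]:.3f}",
                "occluded": int(truth.occluded),
                "distractor_count": truth.distractor_count,
            })
        with open(outdir / "truth.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
        manifest = {
            "n": n, "seed": seed,
            "ranges": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in {**DEFAULT_RANGES, **(ranges or {})}.items()},
            "invocation": invocation,
            "specs": [asdict(s) for s in specs],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=list)
            fh.write("\n")
    return specs, truths, images
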