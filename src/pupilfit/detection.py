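"""Dark-pupil center detection on a single grayscale eye frame.

The pipeline binarizes the frame with a fixed intensity threshold
(dark-pupil convention: the pupil is a dark blob against brighter iris and
sclera), labels the 8-connected dark components, keeps components larger
than a minimum pixel count, extracts each survivor's convex-hull border,
and fits an axis-aligned "upward" ellipse

    x(w) = h - b*sin(w),    y(w) = k + a*cos(w)

to the hull vertices, where ``w`` is the geometric angle of each vertex
about the border centroid.  ``sin`` and ``cos`` are replaced by their
three-term Taylor truncations, which makes both axis fits *linear* in the
unknowns ``(h, b)`` and ``(k, a)``.  Among all admissible fits the one
whose semi-axis ratio is closest to 1 (most circular) wins, and its
``(h, k)`` is reported as the pupil-center point (PCP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError


class DegenerateSegmentError(ValueError):
    """Segment geometry cannot support a hull border or an ellipse fit."""


# --- configuration -----------------------------------------------------------

#: Intensity cut and minimum component size used throughout; pixels strictly
#: below ``threshold`` are candidate-pupil pixels, and only components with
#: strictly more than ``min_segment_size`` pixels are fitted.
@dataclass(frozen=True)
class DetectorConfig:
    threshold: int = 30
    min_segment_size: int = 600

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.min_segment_size < 1:
            raise ValueError("min_segment_size must be >= 1")


# --- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One 8-connected dark component: its label and member pixel coords."""

    label: int
    pixels: np.ndarray  # (n, 2) int array of (x, y), x = column, y = row

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class HullBorder:
    """Convex-hull border of a segment.

    Vertices are ordered counter-clockwise as seen on screen (image
    coordinates, y pointing down), starting from the lexicographically
    smallest vertex.
    """

    vertices: np.ndarray  # (m, 2) float array of (x, y)


@dataclass(frozen=True)
class AngleProfile:
    """Per-vertex angles about the border centroid.

    The reference point is the arithmetic mean of the hull-vertex x and y
    values.  Angles follow the mathematical (y-up) convention despite y-down
    image storage: a vertex straight above the reference on screen is at
    +pi/2.  All angles lie in (-pi, pi], centered on 0 where the Taylor
    truncation is most accurate.
    """

    reference: tuple[float, float]
    angles: np.ndarray  # (m,) float, in (-pi, pi]


@dataclass(frozen=True)
class EllipseFit:
    h: float  # center x, px
    k: float  # center y, px
    a: float  # vertical semi-axis, px
    b: float  # horizontal semi-axis, px
    sse: float  # summed squared residuals of both axis fits
    source_label: int = 0
    source_size: int = 0

    @property
    def circularity(self) -> float:
        """max/min semi-axis ratio; >= 1, equal to 1 for a circle."""
        lo, hi = sorted((self.a, self.b))
        return hi / lo

    @property
    def valid(self) -> bool:
        """Admissible as a pupil candidate: positive finite semi-axes."""
        return (
            math.isfinite(self.h)
            and math.isfinite(self.k)
            and self.a > 0
            and self.b > 0
        )


@dataclass(frozen=True)
class DetectionResult:
    status: str  # "detected" | "no_pupil"
    pcp: tuple[float, float] | None = None
    ellipse: EllipseFit | None = None
    n_candidates: int = 0

    @property
    def detected(self) -> bool:
        return self.status == "detected"


# --- pipeline stages ---------------------------------------------------------


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3:
        # Rec. 601 luminance for color inputs
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        arr = np.clip(np.rint(arr), 0, 255)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


def threshold_image(img: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize: True where intensity is strictly below ``threshold``.

    Strict inequality means threshold 0 always yields an empty mask.
    Returns a boolean array of the image's shape.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return _as_gray(img) < threshold


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def label_segments(mask: np.ndarray) -> list[Segment]:
    """Partition True pixels into maximal 8-connected components.

    Labels run 1..n; segment sizes sum to the mask's True count.  Pixel
    coordinates are (x, y) = (column, row), 0-based.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return []
    ys, xs = np.nonzero(labeled)
    labs = labeled[ys, xs]
    order = np.argsort(labs, kind="stable")
    coords = np.column_stack([xs, ys])[order]
    bounds = np.searchsorted(labs[order], np.arange(1, n + 2))
    return [
        Segment(label=lab, pixels=coords[bounds[lab - 1]:bounds[lab]])
        for lab in range(1, n + 1)
    ]


def filter_segments(segments: list[Segment], min_size: int) -> list[Segment]:
    """Keep segments with strictly more than ``min_size`` pixels."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [s for s in segments if s.size > min_size]


def hull_border(segment: Segment) -> HullBorder:
    """Convex hull of the segment's pixel coordinates.

    Vertices come back counter-clockwise on screen (y-down image axes),
    starting from the lexicographically smallest vertex.  A segment whose
    pixels are all collinear has no 2-D hull and raises
    :class:`DegenerateSegmentError`.
    """
    pts = np.asarray(segment.pixels, dtype=np.float64)
    if len(pts) < 3:
        raise DegenerateSegmentError(f"segment {segment.label}: fewer than 3 pixels")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateSegmentError(
            f"segment {segment.label}: degenerate (collinear) pixel set"
        ) from exc
    # Qhull orders 2-D hull vertices CCW in raw right-handed axes; reversing
    # gives CCW as displayed with y down.
    verts = pts[hull.vertices][::-1]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    return HullBorder(vertices=np.roll(verts, -start, axis=0))


def angle_profile(border: HullBorder) -> AngleProfile:
    """Angle of each hull vertex about the mean-vertex reference point.

    ``w_i = atan2(k_mean - y_i, x_i - h_mean)`` so that angles increase
    counter-clockwise in the conventional y-up sense.
    """
    verts = np.asarray(border.vertices, dtype=np.float64)
    if len(verts) < 3:
        raise DegenerateSegmentError("border needs at least 3 vertices")
    href, kref = verts.mean(axis=0)
    dx = verts[:, 0] - href
    dy = kref - verts[:, 1]
    if np.all((dx == 0) & (dy == 0)):
        raise DegenerateSegmentError("all vertices coincide with the reference")
    angles = np.arctan2(dy, dx)
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] domain
    angles[angles == -np.pi] = np.pi
    return AngleProfile(reference=(float(href), float(kref)), angles=angles)


def parametric_angle(geometric: np.ndarray) -> np.ndarray:
    """Convert geometric vertex angles to the ellipse's parametric angle.

    The upward-ellipse model x = h - b*sin(w), y = k + a*cos(w) places its
    w = 0 point at (h, k + a) — straight below the center on screen.  A
    vertex at geometric angle phi (y-up, from the horizontal) therefore
    corresponds to parameter w = -phi - pi/2: substituting gives
    sin(w) = -cos(phi) and cos(w) = -sin(phi), so the model reproduces the
    vertex position x = h + b*cos(phi), y = k - a*sin(phi) exactly.  The
    map is its own inverse.  Result wrapped to (-pi, pi], so the truncated
    bases stay accurate for the lower half of the border and degrade
    toward the top — the part an eyelid occludes first.
    """
    w = -np.asarray(geometric, dtype=np.float64) - np.pi / 2.0
    w = np.mod(w + np.pi, 2.0 * np.pi) - np.pi  # into (-pi, pi]
    w[w == -np.pi] = np.pi
    return w


def taylor_sin(w: np.ndarray) -> np.ndarray:
    """Three-term Taylor truncation of sin: w - w^3/3! + w^5/5!."""
    w = np.asarray(w, dtype=np.float64)
    return w - w**3 / 6.0 + w**5 / 120.0


def taylor_cos(w: np.ndarray) -> np.ndarray:
    """Three-term Taylor truncation of cos: 1 - w^2/2! + w^4/4!."""
    w = np.asarray(w, dtype=np.float64)
    return 1.0 - w**2 / 2.0 + w**4 / 24.0


def hull_perimeter(border: HullBorder, spacing: float = 1.0) -> np.ndarray:
    """Sample the hull polygon's boundary at roughly ``spacing`` px arc steps.

    The decomposition into sinusoidal components operates on the extracted
    border as a curve, not just its corner points: for compact segments
    (e.g. a rectangular eyelash streak whose hull is 4 corners) or occluded
    pupils (whose truncation chord carries almost no vertices) the corner
    set alone under-determines the fit.  Vertices are always included.
    """
    verts = np.asarray(border.vertices, dtype=np.float64)
    pts = []
    n = len(verts)
    for i in range(n):
        p, q = verts[i], verts[(i + 1) % n]
        steps = max(int(np.ceil(np.hypot(*(q - p)) / spacing)), 1)
        t = np.arange(steps) / steps
        pts.append(p + t[:, None] * (q - p))
    return np.vstack(pts)


def fit_sinusoidal_ellipse(
    border: HullBorder | np.ndarray,
    profile: AngleProfile | None = None,
    *,
    source_label: int = 0,
    source_size: int = 0,
) -> EllipseFit:
    """Least-squares ellipse through border points via truncated bases.

    Each point's geometric angle is converted to the model's parametric
    angle w, and one polynomial is fitted per axis in the monomials of the
    truncated expansions:

        x(w) = c0 + c1*w + c3*w^3 + c5*w^5      (odd terms: sine-like)
        y(w) = d0 + d2*w^2 + d4*w^4             (even terms: cosine-like)

    Matching terms against x = h - b*Ps(w), y = k + a*Pc(w) identifies the
    ellipse: h = c0, b = -c1, a = -2*d2, k = d0 - a (the fitted curve
    passes through (h, k + a) at w = 0).  The fit is exact for noiseless
    data generated from the truncated model, since the bases span Ps and
    Pc.  Fits with a non-positive semi-axis are returned (so callers can
    inspect them) but flagged inadmissible via :attr:`EllipseFit.valid`.

    ``border`` may be a :class:`HullBorder` or a raw (n, 2) point array.
    """
    pts = np.asarray(
        border.vertices if isinstance(border, HullBorder) else border,
        dtype=np.float64,
    )
    if profile is None:
        profile = angle_profile(HullBorder(pts))
    geo = np.asarray(profile.angles, dtype=np.float64)
    if len(pts) < 4:
        raise DegenerateSegmentError("need at least 4 border points to fit")
    if len(np.unique(geo)) < 3:
        raise DegenerateSegmentError("need at least 3 distinct angles to fit")
    w = parametric_angle(geo)

    design_x = np.column_stack([np.ones_like(w), w, w**3, w**5])
    design_y = np.column_stack([np.ones_like(w), w**2, w**4])
    if (
        np.linalg.matrix_rank(design_x) < 4
        or np.linalg.matrix_rank(design_y) < 3
    ):
        raise DegenerateSegmentError("rank-deficient design: angles too clustered")

    cx, res_x, *_ = np.linalg.lstsq(design_x, pts[:, 0], rcond=None)
    cy, res_y, *_ = np.linalg.lstsq(design_y, pts[:, 1], rcond=None)

    h, b = float(cx[0]), float(-cx[1])
    a = float(-2.0 * cy[1])
    k = float(cy[0] - a)

    sse_x = float(res_x[0]) if res_x.size else float(
        np.sum((design_x @ cx - pts[:, 0]) ** 2)
    )
    sse_y = float(res_y[0]) if res_y.size else float(
        np.sum((design_y @ cy - pts[:, 1]) ** 2)
    )
    return EllipseFit(
        h=h, k=k, a=a, b=b,
        sse=sse_x + sse_y,
        source_label=source_label, source_size=source_size,
    )


def select_pupil(fits: list[EllipseFit]) -> EllipseFit | None:
    """Pick the most circular admissible fit.

    The winner minimizes circularity (max/min semi-axis ratio); ties go to
    the larger source segment, then the smaller label, so selection is
    deterministic.  Returns None for an empty candidate list.
    """
    candidates = [f for f in fits if f.valid]
    if not candidates:
        return None
    return min(candidates, key=lambda f: (f.circularity, -f.source_size, f.source_label))


def detect_pupil(img: np.ndarray, config: DetectorConfig | None = None) -> DetectionResult:
    """Full pipeline: grayscale frame in, pupil-center point out.

    Deterministic: identical input and config always yield the identical
    result.  Segments that cannot be fitted (degenerate geometry) are
    skipped rather than aborting the frame.
    """
    if config is None:
        config = DetectorConfig()
    mask = threshold_image(img, config.threshold)
    segments = filter_segments(label_segments(mask), config.min_segment_size)
    fits: list[EllipseFit] = []
    for seg in segments:
        try:
            border = hull_perimeter(hull_border(seg))
            fit = fit_sinusoidal_ellipse(
                border, source_label=seg.label, source_size=seg.size
            )
        except DegenerateSegmentError:
            continue
        if fit.valid:
            fits.append(fit)
    winner = select_pupil(fits)
    if winner is None:
        return DetectionResult(status="no_pupil", n_candidates=len(fits))
    return DetectionResult(
        status="detected",
        pcp=(winner.h, winner.k),
        ellipse=winner,
        n_candidates=len(fits),
    )
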