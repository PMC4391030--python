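"""Accuracy machinery for pupil detectors.

Detection error for a frame is the Euclidean pixel distance between the
detected pupil-center point and the manual (or synthetic ground-truth)
center.  Because errors are nonnegative and concentrated near zero, a
fixed cut in pixels is arbitrary; instead an exponential decay

    f(x) = p0 + ps * exp(-pr * x),    pr > 0

is fitted to the normalized error histogram, and the x-intercept of the
tangent to f at x = 0, (p0 + ps) / (pr * ps), becomes the hit/miss
threshold.  Frames with error strictly below it are hits; the hit fraction
is the detection rate.  Cliff's delta and cumulative error curves support
nonparametric between-method comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class CriterionUnfittableError(ValueError):
    """Error sample cannot support the decay criterion (too few bins)."""


@dataclass(frozen=True)
class DecayFit:
    p0: float  # offset
    ps: float  # scale
    pr: float  # rate, > 0
    threshold: float  # derived hit cut, px
    sse: float = float("nan")


def merge_annotations(p1, p2) -> tuple[float, float]:
    """Mid-point between two raters' selected centers for the same frame."""
    (x1, y1), (x2, y2) = p1, p2
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


def detection_error(pd, pm) -> float:
    """Euclidean pixel distance between detected and reference centers."""
    (xd, yd), (xm, ym) = pd, pm
    return math.hypot(xd - xm, yd - ym)


def decay_curve(x, p0: float, ps: float, pr: float):
    """f(x) = p0 + ps*exp(-pr*x) for x >= 0, 0 below."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, p0 + ps * np.exp(-pr * x), 0.0)


def fit_exponential_decay(errors, bin_width: float = 1.0) -> DecayFit:
    """Fit the decay model to the normalized histogram of errors.

    Errors are binned at ``bin_width`` (px); counts are normalized to a
    density and the model evaluated at bin centers.  Bounded nonlinear
    least squares (rate constrained positive), initialized at
    p0 = min density, ps = max - min density, pr = 1/mean(error).
    Requires at least 4 non-empty bins.
    """
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0 or np.any(e < 0):
        raise ValueError("errors must be a non-empty nonnegative sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = max(int(np.ceil((e.max() + 1e-12) / bin_width)), 1)
    counts, edges = np.histogram(e, bins=nbins, range=(0.0, nbins * bin_width),
                                 density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    if nonempty.sum() < 4:
        raise CriterionUnfittableError(
            f"only {int(nonempty.sum())} non-empty bins; need >= 4"
        )
    mean_e = float(e.mean())
    x0 = np.array([counts.min(), counts.max() - counts.min(),
                   1.0 / mean_e if mean_e > 0 else 1.0])
    x0[1] = max(x0[1], 1e-8)

    def resid(p):
        return decay_curve(centers, *p) - counts

    sol = least_squares(
        resid, x0,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=10_000,
    )
    p0, ps, pr = (float(v) for v in sol.x)
    thr = hit_threshold_value(p0, ps, pr) if ps > 0 and pr > 0 else float("nan")
    return DecayFit(p0=p0, ps=ps, pr=pr, threshold=thr,
                    sse=float(2 * sol.cost))


def hit_threshold_value(p0: float, ps: float, pr: float) -> float:
    """x-intercept of the tangent to the decay at x = 0.

    The tangent has intercept p0 + ps and slope -pr*ps, so the root is
    (p0 + ps) / (pr * ps).
    """
    if ps <= 0 or pr <= 0:
        raise ValueError("hit threshold requires ps > 0 and pr > 0")
    return (p0 + ps) / (pr * ps)


def hit_threshold(fit: DecayFit) -> float:
    return hit_threshold_value(fit.p0, fit.ps, fit.pr)


def classify_hits(errors, threshold: float):
    """Flag each error as hit (strictly below threshold) and rate in %."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0:
        raise ValueError("empty error list")
    flags = e < threshold
    return flags, 100.0 * flags.mean()


def cliffs_delta(xs, ys) -> float:
    """Dominance-based effect size in [-1, 1].

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y).  Computed by
    sorting + rank counting, equivalent to exhaustive pair enumeration.
    Reporting layers typically take the absolute value.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    ys_sorted = np.sort(ys)
    greater = np.searchsorted(ys_sorted, xs, side="left")      # y_j < x_i
    less = ys.size - np.searchsorted(ys_sorted, xs, side="right")  # y_j > x_i
    return float((greater.sum() - less.sum()) / (xs.size * ys.size))


def cumulative_error_curve(errors, grid):
    """Percentage of frames with error <= x, for each x in grid.

    Non-decreasing in x; reaches 100% at max(error).
    """
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0:
        raise ValueError("empty error list")
    grid = np.asarray(grid, dtype=np.float64)
    e_sorted = np.sort(e)
    pct = 100.0 * np.searchsorted(e_sorted, grid, side="right") / e.size
    return np.column_stack([grid, pct])


def evaluate_errors(errors, bin_width: float = 1.0, curve_step: float = 1.0) -> dict:
    """End-to-end accuracy report from an error sample.

    Fits the decay criterion, classifies hits, and summarizes: detection
    rate (%), mean/SD error over all frames, the decay parameters and
    threshold, and the cumulative error curve up to the maximum error.
    """
    e = np.asarray(errors, dtype=np.float64)
    fit = fit_exponential_decay(e, bin_width=bin_width)
    flags, rate = classify_hits(e, fit.threshold)
    grid = np.arange(0.0, float(np.ceil(e.max())) + curve_step, curve_step)
    curve = cumulative_error_curve(e, grid)
    return {
        "n": int(e.size),
        "detection_rate": float(rate),
        "mean_error": float(e.mean()),
        "sd_error": float(e.std(ddof=1)) if e.size > 1 else 0.0,
        "mean_hit_error": float(e[flags].mean()) if flags.any() else float("nan"),
        "decay": {"p0": fit.p0, "ps": fit.ps, "pr": fit.pr,
                  "threshold": fit.threshold},
        "curve": [[float(x), float(p)] for x, p in curve],
    }
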