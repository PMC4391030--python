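"""Independent reference implementations used only to check the library.

Each oracle recomputes a pipeline stage by a different route (exhaustive
search, flood fill, coordinate-descent minimization) so that agreement is
meaningful.  They are deliberately slow and simple.
"""

from __future__ import annotations

import math

import numpy as np


def halfplane_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n^3) convex-hull vertex set by exhaustive half-plane tests.

    A directed pair (p, q) is a hull edge iff every other point lies
    strictly to its left; hull vertices are the endpoints of hull edges.
    Assumes points in general position (no 3 collinear).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p, q = pts[i], pts[j]
            cross = (q[0] - p[0]) * (pts[:, 1] - p[1]) - (q[1] - p[1]) * (pts[:, 0] - p[0])
            others = np.ones(n, dtype=bool)
            others[[i, j]] = False
            if np.all(cross[others] > 0) or np.all(cross[others] < 0):
                verts.add(tuple(p))
                verts.add(tuple(q))
    return verts


def monotone_chain_hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain, written independently of Qhull."""
    pts = sorted(map(tuple, np.asarray(points, dtype=np.float64)))
    if len(pts) <= 2:
        return np.asarray(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.asarray(lower[:-1] + upper[:-1])


def flood_fill_labels(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit BFS flood fill; (x, y) coords."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp = set()
            stack = [(sx, sy)]
            seen[sy, sx] = True
            while stack:
                x, y = stack.pop()
                comp.add((x, y))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        nx, ny = x + dx, y + dy
                        if 0 <= nx < w and 0 <= ny < h and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((nx, ny))
            comps.append(comp)
    return comps


def coordinate_descent_fit(points: np.ndarray, angles_param: np.ndarray,
                           sweeps: int = 120, grid: int = 13):
    """Brute-force minimizer of the per-axis polynomial objectives.

    Minimizes sum((c0 + c1*w + c3*w^3 + c5*w^5 - x)^2) and the even-term
    analogue for y by cyclic per-coordinate grid refinement, never calling
    a linear-algebra solver.  Returns (h, k, a, b) read off term-wise.
    """
    pts = np.asarray(points, dtype=np.float64)
    w = np.asarray(angles_param, dtype=np.float64)

    def minimize(basis: np.ndarray, target: np.ndarray, init: np.ndarray,
                 span: float):
        # pattern search: per-coordinate grid, width halved only when the
        # grid center already wins (keeps progress on narrow valleys)
        coef = init.astype(np.float64).copy()
        widths = np.full(len(coef), span)
        for _ in range(sweeps):
            for i in range(len(coef)):
                trial = coef[i] + np.linspace(-widths[i], widths[i], grid)
                vals = []
                for v in trial:
                    coef[i] = v
                    vals.append(float(np.sum((basis @ coef - target) ** 2)))
                best = int(np.argmin(vals))
                coef[i] = trial[best]
                if best == grid // 2:
                    widths[i] *= 0.5
            if widths.max() < 1e-10:
                break
        return coef

    # Search in a Chebyshev parametrization of the same span (far better
    # conditioned for pattern search), then convert coefficients back to
    # the monomial reading.  Identical objective, no linear solver.
    u = w / math.pi
    t1, t3 = u, 4 * u**3 - 3 * u
    t5 = 16 * u**5 - 20 * u**3 + 5 * u
    t2, t4 = 2 * u**2 - 1, 8 * u**4 - 8 * u**2 + 1
    basis_x = np.column_stack([np.ones_like(u), t1, t3, t5])
    basis_y = np.column_stack([np.ones_like(u), t2, t4])
    span = float(np.ptp(pts)) + 1.0
    ex = minimize(basis_x, pts[:, 0], np.array([pts[:, 0].mean(), 0.0, 0.0, 0.0]), span)
    ey = minimize(basis_y, pts[:, 1], np.array([pts[:, 1].mean(), 0.0, 0.0]), span)
    c1 = (ex[1] - 3 * ex[2] + 5 * ex[3]) / math.pi
    d0 = ey[0] - ey[1] + ey[2]
    d2 = (2 * ey[1] - 8 * ey[2]) / math.pi**2
    h, b = ex[0], -c1
    a = -2.0 * d2
    k = d0 - a
    return h, k, a, b


def pairwise_cliffs_delta(xs, ys) -> float:
    """Exhaustive pair enumeration of the dominance statistic."""
    more = sum(1 for x in xs for y in ys if x > y)
    less = sum(1 for x in xs for y in ys if x < y)
    return (more - less) / (len(xs) * len(ys))


def point_in_convex_polygon(point, vertices, tol: float = 1e-9) -> bool:
    """All edge cross products on one side (or on an edge)."""
    verts = np.asarray(vertices, dtype=np.float64)
    x, y = point
    signs = []
    for i in range(len(verts)):
        p, q = verts[i], verts[(i + 1) % len(verts)]
        signs.append((q[0] - p[0]) * (y - p[1]) - (q[1] - p[1]) * (x - p[0]))
    signs = np.asarray(signs)
    return bool(np.all(signs >= -tol) or np.all(signs <= tol))


def tangent_root(p0: float, ps: float, pr: float) -> float:
    """Root of the line y = (p0 + ps) - pr*ps*x, solved independently."""
    return (p0 + ps) / (pr * ps)


def angle_of(vertex, reference) -> float:
    """Per-vertex arctangent, y-up convention, as a closed form."""
    return math.atan2(reference[1] - vertex[1], vertex[0] - reference[0])
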