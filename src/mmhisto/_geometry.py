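"""Small computational-geometry helpers shared by segmentation and features."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points (0 for degenerate sets)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0


def _circle_two(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    c = (a + b) / 2.0
    return c, float(np.linalg.norm(a - c))


def _circle_three(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumcircle; falls back to the widest pair when (near-)collinear."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        pairs = [(a, b), (a, c), (b, c)]
        return max((_circle_two(p, q) for p, q in pairs), key=lambda cr: cr[1])
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _in_circle(p: np.ndarray, center: np.ndarray, radius: float) -> bool:
    return np.linalg.norm(p - center) <= radius + 1e-9


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle containing all 2-D points (Welzl's algorithm).

    The input is first reduced to its convex hull, so raster-sized point sets
    are cheap.  Deterministic: the hull points are shuffled with a fixed seed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("need an Nx2 nonempty point array")
    pts = np.unique(pts, axis=0)
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    if pts.shape[0] == 2:
        return _circle_two(pts[0], pts[1])
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # collinear sets: Welzl on the raw points still works
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(pts.shape[0])]

    center, radius = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(pts[i], center, radius):
            continue
        # pts[i] is on the boundary of the circle of pts[:i+1]
        center, radius = _circle_two(pts[0], pts[i])
        for j in range(1, i):
            if _in_circle(pts[j], center, radius):
                continue
            center, radius = _circle_two(pts[j], pts[i])
            for k in range(j):
                if not _in_circle(pts[k], center, radius):
                    center, radius = _circle_three(pts[k], pts[j], pts[i])
    return center, radius
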