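"""Smallest enclosing sphere of a 3D point set (Welzl's algorithm).

The walk extent d(W) is the diameter of the minimum sphere enclosing the
atoms a walk visits.  Welzl's randomised recursion runs in expected linear
time; boundary sets of up to four points define candidate spheres through
exact circumsphere solves, with a brute-force fallback for degenerate
(collinear/coplanar) boundary configurations.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["min_enclosing_sphere", "walk_extent_points"]

_EPS = 1e-10


def _circumsphere(pts: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Sphere through all given points (2-4 of them); None if degenerate."""
    k = len(pts)
    if k == 1:
        return pts[0].copy(), 0.0
    if k == 2:
        c = 0.5 * (pts[0] + pts[1])
        return c, float(np.linalg.norm(pts[0] - c))
    p0 = pts[0]
    # center satisfies |c-p0| = |c-pi|  =>  2(pi-p0)·c = |pi|^2-|p0|^2
    A = 2.0 * (pts[1:] - p0)
    b = np.array([p @ p - p0 @ p0 for p in pts[1:]])
    if k == 4:
        try:
            c = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(c)) or np.linalg.cond(A) > 1e12:
            return None
    else:  # k == 3: center also constrained to the points' plane
        normal = np.cross(pts[1] - p0, pts[2] - p0)
        nn = np.linalg.norm(normal)
        if nn < _EPS * max(1.0, np.abs(pts).max()) ** 2:
            return None  # collinear
        A3 = np.vstack([A, normal])
        b3 = np.append(b, normal @ p0)
        c, *_ = np.linalg.lstsq(A3, b3, rcond=None)
    return c, float(np.linalg.norm(pts[0] - c))


def _sphere_of_boundary(boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Minimal sphere with the boundary points on (or inside, if degenerate) it."""
    if not boundary:
        return np.zeros(3), -1.0  # radius -1: contains nothing
    pts = np.array(boundary)
    direct = _circumsphere(pts)
    if direct is not None and len(pts) <= 2:
        return direct
    # degenerate or >2 boundary points: smallest candidate over subsets
    best: tuple[np.ndarray, float] | None = None
    for size in range(1, len(pts) + 1):
        for sub in itertools.combinations(range(len(pts)), size):
            cand = _circumsphere(pts[list(sub)])
            if cand is None:
                continue
            c, r = cand
            if np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + 1e-12) + _EPS):
                if best is None or r < best[1]:
                    best = (c, r)
        if best is not None:
            return best
    raise RuntimeError("no enclosing sphere found for boundary set")  # pragma: no cover


def _welzl(
    points: list[np.ndarray], boundary: list[np.ndarray]
) -> tuple[np.ndarray, float]:
    if not points or len(boundary) == 4:
        return _sphere_of_boundary(boundary)
    p = points[-1]
    c, r = _welzl(points[:-1], boundary)
    if r >= 0 and np.linalg.norm(p - c) <= r + _EPS * max(1.0, r):
        return c, r
    return _welzl(points[:-1], boundary + [p])


def min_enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the smallest sphere enclosing ``points`` (N×3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be N×3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite points")
    pts = np.unique(pts, axis=0)
    order = np.random.default_rng(0).permutation(len(pts))  # fixed: deterministic
    return _welzl([pts[i] for i in order], [])


def walk_extent_points(points: np.ndarray) -> float:
    """Diameter of the minimum enclosing sphere of the given points (Å)."""
    _, r = min_enclosing_sphere(points)
    return 2.0 * r
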