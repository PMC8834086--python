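"""Planar polyline geometry shared by every recognizer.

All costs in this package are Euclidean arclengths in an obstacle-free
plane, so the optimal plan between two points is the straight segment and
its cost is the Euclidean distance.  Polylines are ``(n, 2)`` float arrays;
points are length-2 float arrays (or anything coercible to one).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_point",
    "as_polyline",
    "arclength",
    "optimal_cost",
    "last_point",
    "closest_point",
    "project_onto",
    "prefix",
    "prefix_match",
]


def as_point(p) -> np.ndarray:
    """Coerce to a finite (2,) float array."""
    a = np.asarray(p, dtype=float).reshape(-1)
    if a.shape != (2,):
        raise ValueError(f"a point must have exactly 2 coordinates, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point coordinates must be finite, got {a}")
    return a


def as_polyline(points) -> np.ndarray:
    """Coerce to a finite (n, 2) float array with n >= 1."""
    a = np.asarray(points, dtype=float)
    if a.ndim == 1 and a.shape == (2,):
        a = a.reshape(1, 2)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 1:
        raise ValueError(f"a polyline must be a non-empty sequence of 2D points, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("polyline coordinates must be finite")
    return a


def arclength(polyline) -> float:
    """Total Euclidean length of a polyline; 0 for a single point.

    Consecutive duplicate points are permitted and contribute zero length.
    """
    p = as_polyline(polyline)
    if len(p) == 1:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def optimal_cost(a, b) -> float:
    """Cost of the optimal plan between two points: the straight-line distance."""
    return float(np.linalg.norm(as_point(a) - as_point(b)))


def last_point(polyline) -> np.ndarray:
    """Final point of a polyline."""
    return as_polyline(polyline)[-1].copy()


def _cumlen(p: np.ndarray) -> np.ndarray:
    """Cumulative arclength at each vertex; shape (n,), starts at 0."""
    if len(p) == 1:
        return np.zeros(1)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(seg)))


def project_onto(points, polyline) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project points onto a polyline.

    For each query point returns the distance to the polyline, the arclength
    parameter of the closest point (ties broken toward the earliest segment),
    and the closest point itself.  Projection is onto segment interiors, not
    just vertices.

    Returns ``(dists, params, proj)`` with shapes (m,), (m,), (m, 2).
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    T = as_polyline(polyline)
    if len(T) == 1:
        d = np.linalg.norm(P - T[0], axis=1)
        return d, np.zeros(len(P)), np.tile(T[0], (len(P), 1))
    A = T[:-1]                      # (s, 2) segment starts
    D = T[1:] - A                   # (s, 2) segment vectors
    L2 = np.einsum("ij,ij->i", D, D)  # squared segment lengths
    safe = np.where(L2 > 0, L2, 1.0)
    # t[m, s]: clamped projection parameter of point m on segment s
    W = P[:, None, :] - A[None, :, :]           # (m, s, 2)
    t = np.clip(np.einsum("msj,sj->ms", W, D) / safe, 0.0, 1.0)
    t[:, L2 == 0] = 0.0
    proj = A[None, :, :] + t[..., None] * D[None, :, :]   # (m, s, 2)
    d2 = np.sum((P[:, None, :] - proj) ** 2, axis=2)      # (m, s)
    best = np.argmin(d2, axis=1)
    m_idx = np.arange(len(P))
    cum = _cumlen(T)
    seglen = np.sqrt(L2)
    params = cum[best] + t[m_idx, best] * seglen[best]
    return np.sqrt(d2[m_idx, best]), params, proj[m_idx, best]


def closest_point(p, polyline, cutoff: float | None = None) -> np.ndarray | None:
    """Closest point on a polyline to ``p`` (segment interiors allowed).

    Returns ``None`` when the minimum distance exceeds ``cutoff``
    (``cutoff=None`` means unbounded).
    """
    d, _, proj = project_onto(as_point(p), polyline)
    if cutoff is not None and d[0] > cutoff:
        return None
    return proj[0]


def prefix(polyline, fraction: float) -> np.ndarray:
    """Initial sub-polyline whose arclength is ``fraction`` of the total.

    The cut point is interpolated inside a segment when needed.  Fraction 0
    yields the single start point; fraction 1 yields the full polyline.
    """
    t = as_polyline(polyline)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"prefix fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0:
        return t[:1].copy()
    if fraction == 1.0:
        return t.copy()
    if len(t) < 2:
        raise ValueError("cannot take a proper prefix of a single-point polyline")
    cum = _cumlen(t)
    target = fraction * cum[-1]
    if cum[-1] == 0.0:
        return t[:1].copy()
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(t) - 2)
    seg = cum[i + 1] - cum[i]
    s = 0.0 if seg == 0.0 else (target - cum[i]) / seg
    cut = t[i] + s * (t[i + 1] - t[i])
    if np.allclose(cut, t[i], atol=0.0):
        return t[: i + 1].copy()
    return np.vstack([t[: i + 1], cut])


def prefix_cuts(polyline, fractions) -> tuple[np.ndarray, np.ndarray]:
    """Vertex index and interpolated cut point of each arclength-fraction prefix.

    For fraction ``f``, ``prefix(polyline, f)`` equals
    ``polyline[: idx[k] + 1]`` followed by ``cut[k]`` (the cut point may
    coincide with the last vertex).  Used to evaluate many nested prefixes
    without rebuilding them.
    """
    t = as_polyline(polyline)
    fr = np.asarray(fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    cum = _cumlen(t)
    if cum[-1] == 0.0:
        return np.zeros(len(fr), dtype=int), np.tile(t[0], (len(fr), 1))
    target = fr * cum[-1]
    idx = np.clip(np.searchsorted(cum, target, side="right") - 1, 0, len(t) - 2)
    seg = cum[idx + 1] - cum[idx]
    s = np.where(seg > 0, (target - cum[idx]) / np.where(seg > 0, seg, 1.0), 0.0)
    cuts = t[idx] + s[:, None] * (t[idx + 1] - t[idx])
    return idx, cuts


def batch_prefix_state(obs, idx, cuts, t, tol: float):
    """Prefix-match state of every nested prefix of ``obs`` against ``t``.

    ``idx``/``cuts`` come from :func:`prefix_cuts` on ``obs``.  Returns
    ``(matched, d_cut, proj_cut)``: for each prefix, whether it spatially
    prefix-matches ``t`` (same decision as :func:`prefix_match`), the
    distance from its endpoint to ``t``, and the closest point on ``t`` to
    that endpoint.  Projects each observed point once instead of once per
    prefix.
    """
    O = as_polyline(obs)
    dO, pO, _ = project_onto(O, t)
    ok_dist = np.maximum.accumulate(dO) <= tol
    diffs = np.diff(pO)
    if len(diffs):
        mono = np.concatenate(([True], np.minimum.accumulate(diffs) >= -tol))
    else:
        mono = np.array([True])
    d_cut, p_cut, proj_cut = project_onto(cuts, t)
    matched = (
        (pO[0] <= tol)
        & ok_dist[idx]
        & mono[idx]
        & (d_cut <= tol)
        & (p_cut >= pO[idx] - tol)
    )
    return matched, d_cut, proj_cut


def prefix_match(o, t, tol: float) -> bool:
    """Is ``o`` a spatial prefix of ``t``?

    True iff every point of ``o`` lies within ``tol`` of the polyline ``t``
    and the arclength parameters of their projections onto ``t`` are
    non-decreasing starting at 0.  Monotone progression distinguishes a
    genuine prefix from an observation that merely stays near ``t``
    (e.g., a curl near the start).
    """
    O = as_polyline(o)
    d, params, _ = project_onto(O, t)
    if np.any(d > tol):
        return False
    if params[0] > tol:
        return False
    # parameter jitter of a point within tol of t is itself O(tol)
    return bool(np.all(np.diff(params) >= -tol))
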