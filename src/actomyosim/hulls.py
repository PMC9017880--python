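"""Concave boundary polygons around planar point clouds.

Implements a MATLAB-``boundary``-style shrink-factor interface on top of an
alpha-shape family: triangles of the Delaunay triangulation are discarded in
order of decreasing circumradius.  ``shrink = 0`` keeps every triangle and so
reproduces the convex hull; ``shrink = 1`` keeps the tightest prefix of the
removal sequence for which the remaining region is still a single simple
polygon containing every input point.  Intermediate shrink values interpolate
along that feasible prefix, so increasing the shrink factor never increases
the enclosed area.

Feasibility of each removal is tracked combinatorially (every input point
still a vertex of some kept triangle; edge-adjacency dual graph connected;
Euler characteristic V - E + T = 1, i.e. no holes), and the polygon itself is
assembled once, at the requested shrink level.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = ["concave_boundary"]


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 < 1e-12] = np.inf  # degenerate slivers: drop first
    return r


def _connected(kept: np.ndarray, neighbors: np.ndarray) -> bool:
    idx = np.flatnonzero(kept)
    if len(idx) == 0:
        return False
    seen = np.zeros(len(kept), dtype=bool)
    stack = [idx[0]]
    seen[idx[0]] = True
    while stack:
        t = stack.pop()
        for nb in neighbors[t]:
            if nb >= 0 and kept[nb] and not seen[nb]:
                seen[nb] = True
                stack.append(nb)
    return bool(seen[kept].all())


def _feasible_removals(pts: np.ndarray, tri: Delaunay, order: np.ndarray) -> list:
    """Longest prefix of ``order`` removable while the region stays one
    simple hole-free polygon covering every point; returns the prefix."""
    simplices = tri.simplices
    n_tri = len(simplices)
    vert_count = np.bincount(simplices.ravel(), minlength=len(pts))
    edges: dict = {}
    for t, s in enumerate(simplices):
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = (min(s[i], s[j]), max(s[i], s[j]))
            edges[e] = edges.get(e, 0) + 1
    n_v = int((vert_count > 0).sum())
    n_e = len(edges)
    n_t = n_tri
    kept = np.ones(n_tri, dtype=bool)
    prefix: list = []
    for t in order:
        if n_t == 1:
            break
        s = simplices[t]
        if np.any(vert_count[s] == 1):
            break  # a point would no longer lie on the boundary region
        # tentative O(1) Euler update
        dv = 0
        de = 0
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = (min(s[i], s[j]), max(s[i], s[j]))
            if edges[e] == 1:
                de += 1
        euler = (n_v - dv) - (n_e - de) + (n_t - 1)
        kept[t] = False
        if euler != 1 or not _connected(kept, tri.neighbors):
            kept[t] = True
            break
        vert_count[s] -= 1
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = (min(s[i], s[j]), max(s[i], s[j]))
            edges[e] -= 1
            if edges[e] == 0:
                del edges[e]
        n_e -= de
        n_t -= 1
        prefix.append(t)
    return prefix


def _union_without(pts, simplices, removed) -> Polygon:
    kept = np.ones(len(simplices), dtype=bool)
    kept[list(removed)] = False
    return unary_union([Polygon(pts[s]) for s in simplices[kept]])


def concave_boundary(points, shrink: float = 0.5) -> Optional[Polygon]:
    """Boundary polygon around 2-D ``points`` with the given shrink factor.

    Returns ``None`` for degenerate inputs (< 3 distinct points, collinear
    sets) instead of raising, so batch callers can flag the value invalid.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must lie in [0, 1]")
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) < 3:
        return None
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None  # collinear / degenerate
    simplices = tri.simplices
    if len(simplices) == 0:
        return None
    if shrink == 0.0 or len(simplices) == 1:
        geom = _union_without(pts, simplices, [])
        return geom if isinstance(geom, Polygon) else None

    radii = _circumradii(pts, simplices)
    order = np.argsort(radii)[::-1]
    prefix = _feasible_removals(pts, tri, order)
    idx = int(round(shrink * len(prefix)))
    # geometric verification; back off toward the hull on the rare miss
    while idx >= 0:
        geom = _union_without(pts, simplices, prefix[:idx])
        if isinstance(geom, Polygon) and not geom.interiors:
            return geom
        idx -= 1
    return None
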