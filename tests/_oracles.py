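"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import math

import numpy as np


def brute_force_hull_area(xy: np.ndarray) -> float:
    """Convex-hull area by the O(n^3) orientation test over all point pairs.

    A directed pair (i, j) is a hull edge iff every other point lies on or to
    the left of it; the union of edge endpoints is the hull vertex set, which
    is then angularly sorted and measured by the shoelace formula. Independent
    of any hull-construction algorithm.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 3:
        return 0.0
    verts: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = xy[j] - xy[i]
            cross = d[0] * (xy[:, 1] - xy[i, 1]) - d[1] * (xy[:, 0] - xy[i, 0])
            if np.all(cross >= -1e-9):
                verts.add(i)
                verts.add(j)
    if len(verts) < 3:
        return 0.0
    pts = xy[sorted(verts)]
    c = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    pts = pts[order]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def spherical_law_of_cosines_distance(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float
) -> float:
    """Great-circle distance by the spherical law of cosines (not haversine)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(max(-1.0, min(1.0, c)))
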