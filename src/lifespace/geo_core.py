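"""Spherical geodesy and planar computational-geometry primitives.

All geographic computation in the package goes through this module: great-circle
distances on a sphere of mean radius :data:`EARTH_RADIUS_M`, a local azimuthal
equal-area projection for turning daily fix clouds into planar point sets, and
convex-hull / shoelace-area routines on those planar points.

The sphere (rather than an ellipsoid) is deliberate: the smallest length scale
in the analysis is a 50 m home buffer, where the ellipsoidal correction is
far below GPS noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_008.8
"""Mean Earth radius in meters (IUGG mean radius R1)."""

#: Maximum supported distance from a projection origin, in meters. Points
#: beyond this are treated as outliers that would corrupt area computation.
MAX_PROJECTION_RANGE_M = 200_000.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 geographic coordinate in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError(f"non-finite coordinate: ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range [-90, 90]: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range [-180, 180]: {self.lon}")


@dataclass(frozen=True)
class PlanePoint:
    """A point in a local planar frame, meters east (x) / north (y) of origin."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite plane point: ({self.x}, {self.y})")


class LocalProjection:
    """Lambert azimuthal equal-area projection centered at ``origin``.

    Equal-area by construction, so polygon areas measured in the projected
    plane are faithful (relative error < 0.1 % within 50 km of the origin).
    ``inverse(forward(p))`` reproduces ``p`` to well under 1e-6 degrees in
    that range.
    """

    kind = "azimuthal_equal_area"

    def __init__(self, origin: GeoPoint) -> None:
        self.origin = origin
        self._phi0 = math.radians(origin.lat)
        self._lam0 = math.radians(origin.lon)
        self._sin0 = math.sin(self._phi0)
        self._cos0 = math.cos(self._phi0)

    def forward(self, points: Iterable[GeoPoint]) -> list[PlanePoint]:
        out = []
        for p in points:
            d = geodesic_distance(p, self.origin)
            if d > MAX_PROJECTION_RANGE_M:
                raise ValueError(
                    f"point ({p.lat}, {p.lon}) lies {d / 1000:.1f} km from the "
                    f"projection origin (limit {MAX_PROJECTION_RANGE_M / 1000:.0f} km); "
                    "likely a GPS outlier"
                )
            phi = math.radians(p.lat)
            dlam = math.radians(p.lon) - self._lam0
            cos_c = self._sin0 * math.sin(phi) + self._cos0 * math.cos(phi) * math.cos(dlam)
            denom = 1.0 + cos_c
            if denom <= 1e-12:  # antipode, unreachable given the range guard
                raise ValueError("point antipodal to projection origin")
            k = EARTH_RADIUS_M * math.sqrt(2.0 / denom)
            x = k * math.cos(phi) * math.sin(dlam)
            y = k * (self._cos0 * math.sin(phi) - self._sin0 * math.cos(phi) * math.cos(dlam))
            out.append(PlanePoint(x, y))
        return out

    def inverse(self, points: Iterable[PlanePoint]) -> list[GeoPoint]:
        out = []
        for p in points:
            rho = math.hypot(p.x, p.y)
            if rho < 1e-12:
                out.append(self.origin)
                continue
            c = 2.0 * math.asin(min(1.0, rho / (2.0 * EARTH_RADIUS_M)))
            sin_c, cos_c = math.sin(c), math.cos(c)
            phi = math.asin(cos_c * self._sin0 + p.y * sin_c * self._cos0 / rho)
            lam = self._lam0 + math.atan2(
                p.x * sin_c, rho * self._cos0 * cos_c - p.y * self._sin0 * sin_c
            )
            out.append(GeoPoint(math.degrees(phi), math.degrees(lam)))
        return out


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in meters between two points (haversine).

    Symmetric, non-negative, and zero exactly for identical coordinates.
    """
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon) - math.radians(a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def project_local(points: Sequence[GeoPoint], origin: GeoPoint) -> list[PlanePoint]:
    """Project points to the local equal-area plane centered at ``origin``."""
    return LocalProjection(origin).forward(points)


def _cross(o: PlanePoint, a: PlanePoint, b: PlanePoint) -> float:
    return (a.x - o.x) * (b.y - o.y) - (a.y - o.y) * (b.x - o.x)


def convex_hull(points: Sequence[PlanePoint]) -> list[PlanePoint]:
    """Convex hull via Andrew's monotone chain, counter-clockwise.

    Collinear boundary points are dropped, so the result is the minimal vertex
    set. Degenerate inputs are legal: 0/1/2 distinct points (or all points
    collinear) yield hulls with fewer than 3 vertices.
    """
    pts = sorted(set((p.x, p.y) for p in points))
    if len(pts) <= 2:
        return [PlanePoint(x, y) for x, y in pts]
    pp = [PlanePoint(x, y) for x, y in pts]

    def half(seq: list[PlanePoint]) -> list[PlanePoint]:
        chain: list[PlanePoint] = []
        for p in seq:
            # strict turn test excludes collinear points from the vertex list
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0.0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pp)
    upper = half(pp[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all input points collinear
        return [pp[0], pp[-1]]
    return hull


def is_degenerate_hull(hull: Sequence[PlanePoint]) -> bool:
    """True when the hull has fewer than 3 vertices (no enclosed area)."""
    return len(hull) < 3


def polygon_area(vertices: Sequence[PlanePoint]) -> float:
    """Absolute shoelace area in square meters; degenerate polygons give 0."""
    if len(vertices) < 3:
        return 0.0
    xs = np.array([v.x for v in vertices])
    ys = np.array([v.y for v in vertices])
    return 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))))
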