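"""Home-centered environmental exposures and questionnaire scores.

Spatial exposures are computed from vector map layers (walkable way
polylines, green polygons, categorized points of interest) around each
person's home:

* intersection density — walkable intersections with >= 3 approaches within
  a 1500 m radius;
* green share — percentage of a 500 m disc covered by green polygons;
* walkable reach — count of POIs within the distance coverable in 15 minutes
  at the cohort's mean gait speed (straight-line radius, not isochrones).

Questionnaire variables (service utilization, subjective accessibility,
sidewalk quality) are coded 0-3 and averaged as described in their items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union

from .geo_core import GeoPoint, LocalProjection, geodesic_distance
from .trajectory import HomeAnchor

DEFAULT_INTERSECTION_RADIUS_M = 1500.0
DEFAULT_GREEN_RADIUS_M = 500.0
DEFAULT_REACH_MINUTES = 15.0
NODE_SNAP_TOLERANCE_M = 1.0

TRANSIT_CATEGORIES = frozenset({"bus_stop", "rail_station"})
HEALTH_CATEGORIES = frozenset({"pharmacy", "gp_practice", "hospital"})

UTILIZATION_CODES: Mapping[str, int] = {
    "nie": 0,
    "1/Monat": 1,
    "1/Woche": 2,
    "häufiger": 3,
}
UTILIZATION_SERVICES = (
    "gp",
    "specialist",
    "physiotherapy",
    "nursing_service",
    "speech_or_occupational_therapy",
    "psychotherapy",
    "other",
)
SIDEWALK_LABELS: Mapping[str, int] = {
    "sehr schlecht": 0,
    "eher schlecht": 1,
    "eher gut": 2,
    "sehr gut": 3,
}


@dataclass(frozen=True)
class WaySegment:
    """A street polyline with a walkability flag."""

    way_id: str
    polyline: tuple[GeoPoint, ...]
    walkable: bool = True

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ValueError(f"way {self.way_id}: polyline needs >= 2 vertices")


@dataclass(frozen=True)
class GreenPolygon:
    """A green-area polygon (garden, park, forest, recreation ...)."""

    ring: tuple[GeoPoint, ...]
    category: str = "park"
    holes: tuple[tuple[GeoPoint, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.ring) < 3:
            raise ValueError("green polygon ring needs >= 3 vertices")


@dataclass(frozen=True)
class PoiPoint:
    """A categorized point of interest."""

    pos: GeoPoint
    category: str


@dataclass
class EnvProfile:
    """Per-person home-centered exposures and questionnaire scores."""

    person_id: str
    intersection_density: int = 0
    green_share_pct: float = 0.0
    pt_reach_count: int = 0
    health_reach_count: int = 0
    sidewalk_quality: float | None = None
    utilization_score: float | None = None
    subjective_access: float | None = None


def _snap_key(x: float, y: float, tol: float) -> tuple[int, int]:
    return (round(x / tol), round(y / tol))


def build_way_graph(
    ways: Sequence[WaySegment],
    origin: GeoPoint,
    snap_tolerance_m: float = NODE_SNAP_TOLERANCE_M,
) -> nx.Graph:
    """Planar graph of walkable ways with vertices snapped to a tolerance grid.

    Node attribute ``xy`` holds the projected coordinate (meters from origin).
    """
    proj = LocalProjection(origin)
    g = nx.Graph()
    for way in ways:
        if not way.walkable:
            continue
        planar = proj.forward(way.polyline)
        keys = [_snap_key(p.x, p.y, snap_tolerance_m) for p in planar]
        for p, k in zip(planar, keys):
            if k not in g:
                g.add_node(k, xy=(p.x, p.y))
        for a, b in zip(keys, keys[1:]):
            if a != b:
                g.add_edge(a, b)
    return g


def intersection_density(
    home: HomeAnchor,
    ways: Sequence[WaySegment],
    radius_m: float = DEFAULT_INTERSECTION_RADIUS_M,
    snap_tolerance_m: float = NODE_SNAP_TOLERANCE_M,
) -> int:
    """Walkable intersections (graph degree >= 3) within ``radius_m`` of home."""
    if not ways:
        return 0
    g = build_way_graph(ways, home.pos, snap_tolerance_m)
    count = 0
    for node, data in g.nodes(data=True):
        if g.degree(node) < 3:
            continue
        x, y = data["xy"]
        if math.hypot(x, y) <= radius_m:
            count += 1
    return count


def _to_shapely(poly: GreenPolygon, proj: LocalProjection) -> ShapelyPolygon:
    ring = [(p.x, p.y) for p in proj.forward(poly.ring)]
    holes = [[(p.x, p.y) for p in proj.forward(h)] for h in poly.holes]
    shp = ShapelyPolygon(ring, holes)
    return shp if shp.is_valid else shp.buffer(0)


def green_share(
    home: HomeAnchor,
    polygons: Sequence[GreenPolygon],
    radius_m: float = DEFAULT_GREEN_RADIUS_M,
) -> float:
    """Percent of the disc of ``radius_m`` around home covered by green area.

    Overlapping polygons are unioned first, so green area is never counted
    twice.
    """
    disc = ShapelyPoint(0.0, 0.0).buffer(radius_m, quad_segs=256)
    if not polygons:
        return 0.0
    proj = LocalProjection(home.pos)
    union = unary_union([_to_shapely(p, proj) for p in polygons])
    return 100.0 * union.intersection(disc).area / disc.area


def reach_count(
    home: HomeAnchor,
    pois: Sequence[PoiPoint],
    categories: Iterable[str],
    speed_m_s: float,
    minutes: float = DEFAULT_REACH_MINUTES,
) -> int:
    """POIs of the given categories within a ``minutes``-walk radius of home."""
    if speed_m_s <= 0:
        raise ValueError(f"walking speed must be positive, got {speed_m_s}")
    cats = set(categories)
    radius = speed_m_s * 60.0 * minutes
    return sum(
        1
        for poi in pois
        if poi.category in cats and geodesic_distance(poi.pos, home.pos) <= radius
    )


def utilization_score(answers: Mapping[str, str | int | None]) -> float | None:
    """Mean utilization code over answered services.

    Accepts response labels (``nie``, ``1/Monat``, ``1/Woche``, ``häufiger``)
    or their numeric codes 0-3. Unanswered services are skipped; if all are
    missing the score is missing (None).
    """
    codes = []
    for service, answer in answers.items():
        if answer is None or (isinstance(answer, float) and math.isnan(answer)):
            continue
        if isinstance(answer, str):
            if answer not in UTILIZATION_CODES:
                raise ValueError(
                    f"unknown utilization response {answer!r} for {service!r}; "
                    f"expected one of {sorted(UTILIZATION_CODES)}"
                )
            codes.append(UTILIZATION_CODES[answer])
        else:
            code = int(answer)
            if code not in (0, 1, 2, 3):
                raise ValueError(f"utilization code out of range 0-3: {answer!r}")
            codes.append(code)
    return sum(codes) / len(codes) if codes else None


def subjective_access_score(
    gp_item: int | None, bus_item: int | None
) -> float | None:
    """Mean of the two accessibility items (codes 0-3); one may be missing."""
    codes = []
    for name, item in (("gp_item", gp_item), ("bus_item", bus_item)):
        if item is None or (isinstance(item, float) and math.isnan(item)):
            continue
        if int(item) not in (0, 1, 2, 3):
            raise ValueError(f"{name} out of range 0-3: {item!r}")
        codes.append(int(item))
    return sum(codes) / len(codes) if codes else None


def sidewalk_quality_score(code: int | str) -> int:
    """Validate/convert the sidewalk-quality item (label or code) to 0-3."""
    if isinstance(code, str):
        if code not in SIDEWALK_LABELS:
            raise ValueError(
                f"unknown sidewalk label {code!r}; expected one of {sorted(SIDEWALK_LABELS)}"
            )
        return SIDEWALK_LABELS[code]
    value = int(code)
    if value not in (0, 1, 2, 3):
        raise ValueError(f"sidewalk quality code out of range 0-3: {code!r}")
    return value


def compute_env_profile(
    home: HomeAnchor,
    ways: Sequence[WaySegment],
    greens: Sequence[GreenPolygon],
    pois: Sequence[PoiPoint],
    speed_m_s: float,
    questionnaire: Mapping[str, object] | None = None,
    transit_categories: Iterable[str] = TRANSIT_CATEGORIES,
    health_categories: Iterable[str] = HEALTH_CATEGORIES,
) -> EnvProfile:
    """Assemble the full exposure profile for one person.

    ``questionnaire`` may carry ``utilization`` (mapping), ``gp_item``,
    ``bus_item`` and ``sidewalk_quality`` entries.
    """
    q = dict(questionnaire or {})
    profile = EnvProfile(
        person_id=home.person_id,
        intersection_density=intersection_density(home, ways),
        green_share_pct=green_share(home, greens),
        pt_reach_count=reach_count(home, pois, transit_categories, speed_m_s),
        health_reach_count=reach_count(home, pois, health_categories, speed_m_s),
    )
    if "sidewalk_quality" in q:
        profile.sidewalk_quality = float(sidewalk_quality_score(q["sidewalk_quality"]))
    if "utilization" in q:
        profile.utilization_score = utilization_score(q["utilization"])
    if "gp_item" in q or "bus_item" in q:
        profile.subjective_access = subjective_access_score(
            q.get("gp_item"), q.get("bus_item")
        )
    return profile


def env_table(profiles: Sequence[EnvProfile]) -> pd.DataFrame:
    """Per-person EnvProfile table in the package's CSV dialect."""
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "intersection_density": p.intersection_density,
                "green_share_pct": p.green_share_pct,
                "pt_reach_count": p.pt_reach_count,
                "health_reach_count": p.health_reach_count,
                "sidewalk_quality": p.sidewalk_quality,
                "utilization_score": p.utilization_score,
                "subjective_access": p.subjective_access,
            }
            for p in profiles
        ]
    )


# ---------------------------------------------------------------------------
# GeoJSON ingestion


def read_geojson_layers(
    source: str | dict,
) -> tuple[list[WaySegment], list[GreenPolygon], list[PoiPoint]]:
    """Split a GeoJSON FeatureCollection into way / green / POI layers.

    LineString features carry a boolean ``walkable`` property; Polygon
    features a ``green_category``; Point features a ``category``.
    """
    import json
    from pathlib import Path

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            fc = json.load(fh)
    else:
        fc = source
    ways: list[WaySegment] = []
    greens: list[GreenPolygon] = []
    pois: list[PoiPoint] = []
    for i, feat in enumerate(fc.get("features", [])):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "LineString":
            pts = tuple(GeoPoint(lat, lon) for lon, lat in coords)
            ways.append(
                WaySegment(
                    way_id=str(props.get("way_id", i)),
                    polyline=pts,
                    walkable=bool(props.get("walkable", True)),
                )
            )
        elif gtype == "Polygon":
            ring = tuple(GeoPoint(lat, lon) for lon, lat in coords[0])
            holes = tuple(
                tuple(GeoPoint(lat, lon) for lon, lat in hole) for hole in coords[1:]
            )
            greens.append(
                GreenPolygon(
                    ring=ring,
                    category=str(props.get("green_category", "park")),
                    holes=holes,
                )
            )
        elif gtype == "Point":
            lon, lat = coords
            pois.append(PoiPoint(GeoPoint(lat, lon), str(props.get("category", "poi"))))
    return ways, greens, pois
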