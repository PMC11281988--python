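"""Daily out-of-home mobility indicators and stop/trip segmentation.

Two indicators are computed per person-day:

* **Time out of home (TOH)** — cumulative minutes spent beyond the home
  buffer. An inter-fix interval counts when both endpoint fixes are out of
  home and the interval is no longer than a configurable gap cap (default
  10 min), so long recording holes are never silently counted as time out.
* **Convex-hull area (km²)** — area of the convex hull of *all* of the day's
  fixes (including at-home ones), measured in a local equal-area projection
  centered at the day's centroid.

A reconstructed stop/trip classifier segments each day into dwell periods
(stops) and movement periods (trips).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geo_core import (
    GeoPoint,
    PlanePoint,
    convex_hull,
    geodesic_distance,
    polygon_area,
    project_local,
)
from .trajectory import GpsFix, HomeAnchor, TrackDay, coverage_hours, is_valid_day

DEFAULT_MAX_GAP_MIN = 10.0


@dataclass(frozen=True)
class DailyMobility:
    """Per person-day mobility indicators."""

    person_id: str
    mobility_date: object
    toh_min: float
    chull_km2: float
    n_fixes: int
    coverage_hours: int
    valid: bool


@dataclass(frozen=True)
class Segment:
    """A stop (dwell) or trip (movement) span of one day's recording."""

    kind: Literal["stop", "trip"]
    start: datetime
    end: datetime
    anchor: GeoPoint

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")


def is_out_of_home(fix: GpsFix, home: HomeAnchor) -> bool:
    """True when the fix lies strictly beyond the home buffer.

    A fix at exactly the buffer distance counts as home.
    """
    return geodesic_distance(fix.pos, home.pos) > home.buffer_m


def time_out_of_home(
    day: TrackDay, home: HomeAnchor, max_gap_min: float = DEFAULT_MAX_GAP_MIN
) -> float:
    """Cumulative out-of-home minutes of the day (fractional).

    Sums the durations of consecutive-fix intervals whose *both* endpoints are
    out of home and whose length does not exceed ``max_gap_min`` minutes.
    """
    if len(day.fixes) < 2:
        if day.fixes:
            warnings.warn(
                f"{day.person_id} {day.mobility_date}: fewer than 2 fixes, TOH = 0",
                stacklevel=2,
            )
        return 0.0
    out = [is_out_of_home(f, home) for f in day.fixes]
    total_min = 0.0
    for i in range(len(day.fixes) - 1):
        if not (out[i] and out[i + 1]):
            continue
        gap_min = (day.fixes[i + 1].t - day.fixes[i].t).total_seconds() / 60.0
        if gap_min <= max_gap_min:
            total_min += gap_min
    return total_min


def day_centroid(day: TrackDay) -> GeoPoint:
    """Mean-coordinate centroid of the day's fixes (projection origin)."""
    if not day.fixes:
        raise ValueError("cannot take the centroid of an empty day")
    return GeoPoint(
        sum(f.pos.lat for f in day.fixes) / len(day.fixes),
        sum(f.pos.lon for f in day.fixes) / len(day.fixes),
    )


def daily_convex_hull_km2(day: TrackDay) -> float:
    """Convex-hull area of all the day's fixes, in km².

    Days with fewer than 3 non-collinear fixes have zero area.
    """
    if len(day.fixes) < 3:
        return 0.0
    planar = project_local([f.pos for f in day.fixes], day_centroid(day))
    return polygon_area(convex_hull(planar)) / 1e6


def _medoid_index(points: Sequence[PlanePoint]) -> int:
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    dist_sums = (
        np.abs(xs[:, None] - xs[None, :]) ** 2 + np.abs(ys[:, None] - ys[None, :]) ** 2
    ).sum(axis=1)
    return int(np.argmin(dist_sums))


def segment_stops_trips(
    day: TrackDay, stop_radius_m: float = 50.0, min_dwell_min: float = 5.0
) -> list[Segment]:
    """Segment a day's recording into stops and trips.

    Maximal runs of fixes that all stay within ``stop_radius_m`` of the run's
    medoid and span at least ``min_dwell_min`` minutes become stops; everything
    between stops becomes a trip. The returned segments tile the recorded time
    span with no overlaps.
    """
    fixes = day.fixes
    if len(fixes) < 2:
        return []
    planar = project_local([f.pos for f in fixes], day_centroid(day))

    def within_radius(idx: list[int]) -> bool:
        pts = [planar[i] for i in idx]
        m = pts[_medoid_index(pts)]
        return all(math.hypot(p.x - m.x, p.y - m.y) <= stop_radius_m for p in pts)

    # greedy maximal dwell runs
    stop_runs: list[tuple[int, int]] = []  # inclusive index ranges
    i = 0
    n = len(fixes)
    while i < n:
        j = i
        while j + 1 < n and within_radius(list(range(i, j + 2))):
            j += 1
        span_min = (fixes[j].t - fixes[i].t).total_seconds() / 60.0
        if j > i and span_min >= min_dwell_min:
            stop_runs.append((i, j))
            i = j + 1
        else:
            i += 1

    segments: list[Segment] = []

    def add_trip(a: int, b: int) -> None:
        if fixes[a].t >= fixes[b].t:
            return
        mid = planar[(a + b) // 2]
        anchor = _unproject_one(mid, day)
        segments.append(Segment("trip", fixes[a].t, fixes[b].t, anchor))

    cursor = 0
    for a, b in stop_runs:
        if a > cursor:
            add_trip(cursor, a)
        pts = [planar[i] for i in range(a, b + 1)]
        medoid = _unproject_one(pts[_medoid_index(pts)], day)
        segments.append(Segment("stop", fixes[a].t, fixes[b].t, medoid))
        cursor = b
    if cursor < n - 1:
        add_trip(cursor, n - 1)
    return segments


def _unproject_one(p: PlanePoint, day: TrackDay) -> GeoPoint:
    from .geo_core import LocalProjection

    return LocalProjection(day_centroid(day)).inverse([p])[0]


def compute_daily_mobility(
    day: TrackDay,
    home: HomeAnchor,
    max_gap_min: float = DEFAULT_MAX_GAP_MIN,
    validity_rule: Literal["distinct", "cumulative"] = "distinct",
) -> DailyMobility:
    """Bundle the day's indicators; computed (and flagged) even for invalid days."""
    return DailyMobility(
        person_id=day.person_id,
        mobility_date=day.mobility_date,
        toh_min=time_out_of_home(day, home, max_gap_min=max_gap_min),
        chull_km2=daily_convex_hull_km2(day),
        n_fixes=len(day.fixes),
        coverage_hours=coverage_hours(day, rule=validity_rule),
        valid=is_valid_day(day, rule=validity_rule),
    )


def mobility_table(records: Sequence[DailyMobility]) -> pd.DataFrame:
    """Per person-day indicator table in the package's CSV dialect."""
    return pd.DataFrame(
        [
            {
                "person_id": r.person_id,
                "mobility_date": r.mobility_date,
                "toh_min": r.toh_min,
                "chull_km2": r.chull_km2,
                "n_fixes": r.n_fixes,
                "coverage_hours": r.coverage_hours,
                "valid": r.valid,
            }
            for r in records
        ]
    )


def summarize_mobility(days: Sequence[DailyMobility] | pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of both indicators over valid days.

    Invalid days are excluded; with a single valid day the SD is reported as 0
    and flagged via ``sd_defined = False``.
    """
    df = days if isinstance(days, pd.DataFrame) else mobility_table(list(days))
    valid = df[df["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("no valid days to summarize")
    rows = []
    sd_defined = len(valid) > 1
    for col, label in [("toh_min", "toh_min"), ("chull_km2", "chull_km2")]:
        sd = float(valid[col].std(ddof=1)) if sd_defined else 0.0
        rows.append(
            {
                "indicator": label,
                "n_days": len(valid),
                "mean": float(valid[col].mean()),
                "sd": sd,
                "sd_defined": sd_defined,
            }
        )
    return pd.DataFrame(rows)
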