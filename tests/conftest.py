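from __future__ import annotations

from datetime import date, datetime, timedelta
from zoneinfo import ZoneInfo

import pytest

from lifespace.geo_core import GeoPoint, LocalProjection, PlanePoint
from lifespace.trajectory import GpsFix, HomeAnchor, TrackDay

TZ = ZoneInfo("Europe/Berlin")
HOME = GeoPoint(52.5, 12.5)


@pytest.fixture
def home_anchor() -> HomeAnchor:
    return HomeAnchor("p1", HOME, buffer_m=50.0)


def make_day(
    points: list[tuple[float, float, float]],
    home: GeoPoint = HOME,
    person_id: str = "p1",
    day: date = date(2022, 7, 1),
    start_hour: int = 10,
) -> TrackDay:
    """Build a TrackDay from (minutes_offset, x_m, y_m) tuples around ``home``.

    Planar offsets are converted to WGS84 via the local equal-area projection,
    so a point at (0, 100) sits ~100 m geodesically north of home.
    """
    proj = LocalProjection(home)
    base = datetime(day.year, day.month, day.day, start_hour, 0, tzinfo=TZ)
    fixes = []
    for minutes, x, y in points:
        pos = proj.inverse([PlanePoint(x, y)])[0]
        fixes.append(GpsFix(person_id, base + timedelta(minutes=minutes), pos))
    fixes.sort(key=lambda f: f.t)
    return TrackDay(person_id, day, fixes)
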