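"""GPS fix ingestion and mobility-day construction.

A *mobility day* runs from 03:00 local time to 02:59 the next morning, so that
activity stretching past midnight is attributed to the preceding day. A day is
*valid* when at least 8 hours of GPS data were recorded; by default this means
8 distinct clock hours containing at least one fix (a rule robust to differing
fix rates), with a cumulative-duration alternative available via
``rule="cumulative"``.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

from .geo_core import GeoPoint

logger = logging.getLogger(__name__)

DEFAULT_TIMEZONE = "Europe/Berlin"
DAY_ANCHOR_HOURS = 3
MIN_VALID_COVERAGE_HOURS = 8


@dataclass(frozen=True)
class GpsFix:
    """One timestamped WGS84 position of one person."""

    person_id: str
    t: datetime
    pos: GeoPoint
    accuracy_m: float | None = None

    def __post_init__(self) -> None:
        if self.t.tzinfo is None:
            raise ValueError(f"fix timestamp must be timezone-aware: {self.t!r}")


@dataclass
class TrackDay:
    """All fixes of one person falling on one mobility date, time-ordered."""

    person_id: str
    mobility_date: date
    fixes: list[GpsFix] = field(default_factory=list)

    @property
    def coverage_hours(self) -> int:
        return coverage_hours(self)

    @property
    def valid(self) -> bool:
        return is_valid_day(self)


@dataclass(frozen=True)
class HomeAnchor:
    """A person's home coordinate with the out-of-home buffer radius."""

    person_id: str
    pos: GeoPoint
    buffer_m: float = 50.0

    def __post_init__(self) -> None:
        if self.buffer_m <= 0:
            raise ValueError(f"buffer_m must be positive, got {self.buffer_m}")


def read_gps_table(
    source: str | Path,
    timezone: str = DEFAULT_TIMEZONE,
    person_id: str | None = None,
) -> list[GpsFix]:
    """Read GPS fixes from a CSV table or a GPX 1.1 track file.

    CSV columns: ``person_id, timestamp, lat, lon[, accuracy_m]`` with ISO-8601
    timestamps. Naive timestamps are localized to ``timezone``. Fixes are
    returned sorted per person by time; exact duplicates (same person, same
    timestamp) keep the first occurrence.

    For GPX input the person id is taken from ``person_id`` or, failing that,
    the file stem.
    """
    source = Path(source)
    if source.suffix.lower() == ".gpx":
        return _read_gpx(source, timezone, person_id or source.stem)
    return _read_csv(source, timezone)


def _localize(ts: pd.Timestamp, tz: ZoneInfo) -> datetime:
    dt = ts.to_pydatetime()
    return dt.replace(tzinfo=tz) if dt.tzinfo is None else dt


def _read_csv(path: Path, timezone: str) -> list[GpsFix]:
    tz = ZoneInfo(timezone)
    df = pd.read_csv(path, dtype={"person_id": str})
    if df.empty:
        warnings.warn(f"GPS table {path} contains no rows", stacklevel=3)
        return []
    required = {"person_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    fixes: list[GpsFix] = []
    for row in df.itertuples():
        rowno = row.Index + 2  # 1-based, counting the header
        try:
            ts = pd.Timestamp(row.timestamp)
            pos = GeoPoint(float(row.lat), float(row.lon))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {rowno}: {exc}") from exc
        if pd.isna(ts):
            raise ValueError(f"{path} row {rowno}: unparseable timestamp {row.timestamp!r}")
        acc = getattr(row, "accuracy_m", None)
        acc = float(acc) if acc is not None and not pd.isna(acc) else None
        fixes.append(GpsFix(str(row.person_id), _localize(ts, tz), pos, acc))
    return _sort_dedup(fixes)


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx(path: Path, timezone: str, person_id: str) -> list[GpsFix]:
    tz = ZoneInfo(timezone)
    root = ET.parse(path).getroot()
    fixes: list[GpsFix] = []
    for trkpt in root.iter(f"{_GPX_NS}trkpt"):
        time_el = trkpt.find(f"{_GPX_NS}time")
        if time_el is None or time_el.text is None:
            raise ValueError(f"{path}: trkpt without <time> element")
        ts = pd.Timestamp(time_el.text)
        pos = GeoPoint(float(trkpt.attrib["lat"]), float(trkpt.attrib["lon"]))
        fixes.append(GpsFix(person_id, _localize(ts, tz), pos))
    if not fixes:
        warnings.warn(f"GPX file {path} contains no track points", stacklevel=3)
    return _sort_dedup(fixes)


def _sort_dedup(fixes: Iterable[GpsFix]) -> list[GpsFix]:
    out: list[GpsFix] = []
    seen: set[tuple[str, datetime]] = set()
    for fix in sorted(fixes, key=lambda f: (f.person_id, f.t)):
        key = (fix.person_id, fix.t)
        if key in seen:
            continue
        seen.add(key)
        out.append(fix)
    return out


def mobility_date_of(t: datetime, timezone: str = DEFAULT_TIMEZONE) -> date:
    """Calendar date owning timestamp ``t`` under the 03:00 day anchor.

    Fixes between midnight and 02:59 belong to the previous calendar date.
    """
    if t.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    local = t.astimezone(ZoneInfo(timezone))
    return (local - timedelta(hours=DAY_ANCHOR_HOURS)).date()


def split_days(
    fixes: Sequence[GpsFix], timezone: str = DEFAULT_TIMEZONE
) -> list[TrackDay]:
    """Partition per-person fixes into TrackDays under the 03:00 rule.

    Every input fix lands in exactly one day; days without fixes do not
    appear. Output is ordered by (person, date).
    """
    buckets: dict[tuple[str, date], list[GpsFix]] = {}
    for fix in fixes:
        key = (fix.person_id, mobility_date_of(fix.t, timezone))
        buckets.setdefault(key, []).append(fix)
    days = []
    for (pid, d), day_fixes in sorted(buckets.items()):
        days.append(TrackDay(pid, d, sorted(day_fixes, key=lambda f: f.t)))
    return days


def coverage_hours(
    day: TrackDay,
    rule: Literal["distinct", "cumulative"] = "distinct",
    max_gap_min: float = 10.0,
) -> int:
    """Hours of GPS recording within the mobility day.

    ``distinct`` (default): number of distinct local clock hours containing at
    least one fix. ``cumulative``: total recorded duration, counting inter-fix
    intervals no longer than ``max_gap_min``, floored to whole hours.
    """
    if not day.fixes:
        return 0
    if rule == "distinct":
        hours = {(f.t.date(), f.t.hour) for f in day.fixes}
        return len(hours)
    if rule == "cumulative":
        total = timedelta()
        for a, b in zip(day.fixes, day.fixes[1:]):
            gap = b.t - a.t
            if gap <= timedelta(minutes=max_gap_min):
                total += gap
        return int(total.total_seconds() // 3600)
    raise ValueError(f"unknown coverage rule: {rule!r}")


def is_valid_day(
    day: TrackDay, rule: Literal["distinct", "cumulative"] = "distinct"
) -> bool:
    """True when the day reaches the 8-hour recording threshold."""
    return coverage_hours(day, rule=rule) >= MIN_VALID_COVERAGE_HOURS


def read_homes_table(path: str | Path, buffer_m: float = 50.0) -> dict[str, HomeAnchor]:
    """Read per-person home anchors from CSV (person_id, lat, lon[, buffer_m])."""
    df = pd.read_csv(path, dtype={"person_id": str})
    homes = {}
    for row in df.itertuples():
        buf = float(getattr(row, "buffer_m", buffer_m) or buffer_m)
        homes[str(row.person_id)] = HomeAnchor(
            str(row.person_id), GeoPoint(float(row.lat), float(row.lon)), buf
        )
    return homes
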