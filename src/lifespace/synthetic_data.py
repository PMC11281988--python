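"""Seeded generators for cohorts, environments, outcomes and GPS trajectories.

Everything here is a pure function of ``(config, seed)``: simulating twice
with the same seed reproduces identical tables, layers and traces. The
generators exist so every upstream stage of the pipeline can be exercised
against known ground truth — cohort tables with chosen covariate marginals,
street-grid environments whose exposure metrics can be enumerated by hand,
day-level Poisson outcomes from a random-intercept log-linear model with
chosen coefficients, and GPS day traces whose time-out-of-home is controlled
to the minute.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .environment import GreenPolygon, PoiPoint, WaySegment
from .geo_core import GeoPoint, LocalProjection, PlanePoint
from .trajectory import DEFAULT_TIMEZONE, GpsFix, HomeAnchor, TrackDay


@dataclass
class SimConfig:
    """Ground-truth parameters for all generators.

    Covariate marginal defaults follow the emulated cohort: mean age 81.5
    (SD 4.1) truncated at the 75-year inclusion bound, 56.1 % women, 57.1 %
    cohabiting, 88.2 % active drivers, and so on. ``true_beta`` maps design
    terms (``intercept``, covariate column names, ``counter``) to log-scale
    coefficients of the generating Poisson model.
    """

    n_persons: int = 200
    days_per_person: int = 7
    seed: int = 0
    timezone: str = DEFAULT_TIMEZONE

    # cohort marginals: continuous as (mean, sd, lower, upper)
    age: tuple[float, float, float, float] = (81.5, 4.1, 75.0, 103.0)
    health_literacy: tuple[float, float, float, float] = (40.6, 5.8, 0.0, 50.0)
    ksk12: tuple[float, float, float, float] = (43.9, 11.3, 0.0, 100.0)
    psk12: tuple[float, float, float, float] = (58.4, 4.9, 0.0, 100.0)
    social_network_satisfaction: tuple[float, float, float, float] = (9.6, 1.0, 0.0, 10.0)
    p_female: float = 0.561
    p_cohabiting: float = 0.571
    p_active_driving: float = 0.882
    education_probs: tuple[float, float, float] = (0.027, 0.401, 0.572)  # low/mid/high

    # outcome model
    true_beta: dict[str, float] = field(
        default_factory=lambda: {"intercept": 5.7, "counter": 0.0}
    )
    true_tau00: float = 0.5

    # trajectory generation
    fix_interval_s: float = 60.0
    gps_noise_sd_m: float = 5.0
    dropout_fraction: float = 0.0
    home_buffer_m: float = 50.0

    # environment generation
    origin: tuple[float, float] = (52.5, 12.5)
    grid_n: int = 7
    grid_spacing_m: float = 500.0
    walking_speed_m_s: float = 1.0
    n_green: int = 6
    green_size_m: float = 300.0
    poi_counts: dict[str, int] = field(
        default_factory=lambda: {
            "bus_stop": 8,
            "rail_station": 1,
            "pharmacy": 3,
            "gp_practice": 3,
            "hospital": 1,
            "shop": 6,
        }
    )

    def __post_init__(self) -> None:
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if self.true_tau00 < 0:
            raise ValueError("true_tau00 must be >= 0")
        for name, p in [
            ("p_female", self.p_female),
            ("p_cohabiting", self.p_cohabiting),
            ("p_active_driving", self.p_active_driving),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")


@dataclass
class SimTruth:
    """Generating parameters and latent draws behind one simulated outcome table."""

    beta: dict[str, float]
    tau00: float
    random_intercepts: pd.Series
    expected_counts: np.ndarray


def _shifted_truncnorm_loc(mean: float, sd: float, lower: float, upper: float) -> float:
    """Location making truncnorm(loc, sd) on [lower, upper] have the target mean.

    A plain truncated normal with loc = target mean is biased away from the
    nearer bound (e.g. the 75-year age floor would inflate the mean by
    ~0.5 y); solving for the location keeps the realized marginal honest.
    """

    def trunc_mean(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    lo, hi = lower - 10 * sd, upper + 30 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - mean, lo, hi, xtol=1e-10))


def _draw_truncnorm(
    rng: np.random.Generator, n: int, spec: tuple[float, float, float, float]
) -> np.ndarray:
    mean, sd, lower, upper = spec
    loc = _shifted_truncnorm_loc(mean, sd, lower, upper)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a person-level covariate table from the configured marginals.

    Covariates are drawn independently (no correlation structure). All ages
    respect the 75-year floor while the sample mean matches the configured
    marginal mean.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_persons
    probs = np.asarray(config.education_probs, dtype=float)
    probs = probs / probs.sum()
    education = rng.choice(["low", "middle", "high"], size=n, p=probs)
    df = pd.DataFrame(
        {
            "person_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "age": _draw_truncnorm(rng, n, config.age),
            "sex_female": rng.binomial(1, config.p_female, n),
            "cohabiting": rng.binomial(1, config.p_cohabiting, n),
            "education": education,
            "ksk12": _draw_truncnorm(rng, n, config.ksk12),
            "psk12": _draw_truncnorm(rng, n, config.psk12),
            "health_literacy": _draw_truncnorm(rng, n, config.health_literacy),
            "social_network_satisfaction": _draw_truncnorm(
                rng, n, config.social_network_satisfaction
            ),
            "active_driving": rng.binomial(1, config.p_active_driving, n),
        }
    )
    df["edu_middle"] = (df["education"] == "middle").astype(int)
    df["edu_high"] = (df["education"] == "high").astype(int)
    return df


def simulate_environment(
    config: SimConfig, seed: int | None = None
) -> tuple[list[WaySegment], list[GreenPolygon], list[PoiPoint]]:
    """Generate a rectangular walkable street grid, green polygons and POIs.

    The grid has ``grid_n`` x ``grid_n`` nodes at ``grid_spacing_m`` with
    streets sharing vertices at every node, so intersection counts can be
    enumerated by hand. Green squares and POIs are placed uniformly within
    the grid extent.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    origin = GeoPoint(*config.origin)
    proj = LocalProjection(origin)
    n, s = config.grid_n, config.grid_spacing_m
    half = (n - 1) * s / 2.0

    def geo(x: float, y: float) -> GeoPoint:
        return proj.inverse([PlanePoint(x, y)])[0]

    ways: list[WaySegment] = []
    for i in range(n):  # horizontal streets
        pts = tuple(geo(j * s - half, i * s - half) for j in range(n))
        ways.append(WaySegment(way_id=f"h{i}", polyline=pts, walkable=True))
    for j in range(n):  # vertical streets
        pts = tuple(geo(j * s - half, i * s - half) for i in range(n))
        ways.append(WaySegment(way_id=f"v{j}", polyline=pts, walkable=True))

    greens: list[GreenPolygon] = []
    for _ in range(config.n_green):
        cx, cy = rng.uniform(-half, half, size=2)
        h = config.green_size_m / 2.0
        ring = tuple(
            geo(cx + dx, cy + dy)
            for dx, dy in [(-h, -h), (h, -h), (h, h), (-h, h), (-h, -h)]
        )
        greens.append(GreenPolygon(ring=ring, category="park"))

    pois: list[PoiPoint] = []
    for category, count in sorted(config.poi_counts.items()):
        for _ in range(count):
            px, py = rng.uniform(-half, half, size=2)
            pois.append(PoiPoint(geo(px, py), category))
    return ways, greens, pois


def simulate_homes(
    config: SimConfig, seed: int | None = None
) -> dict[str, HomeAnchor]:
    """Place one home per person uniformly within the inner grid extent."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2_000_003)
    proj = LocalProjection(GeoPoint(*config.origin))
    half = (config.grid_n - 1) * config.grid_spacing_m / 2.0
    homes = {}
    for i in range(1, config.n_persons + 1):
        pid = f"P{i:04d}"
        x, y = rng.uniform(-half * 0.8, half * 0.8, size=2)
        pos = proj.inverse([PlanePoint(x, y)])[0]
        homes[pid] = HomeAnchor(pid, pos, config.home_buffer_m)
    return homes


def simulate_daily_counts(
    cohort: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    env: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw day-level Poisson outcomes from the random-intercept model.

    ``eta = beta0 + x' beta + beta_counter * counter + b_i`` with
    ``b_i ~ Normal(0, tau00)`` and ``y ~ Poisson(exp(eta))``. Covariate terms
    of ``config.true_beta`` are looked up by column name in ``cohort`` (and
    ``env`` when given).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3_000_003)
    beta = dict(config.true_beta)
    if "intercept" not in beta:
        raise ValueError("true_beta must contain an 'intercept' term")
    merged = cohort.copy()
    if env is not None:
        merged = merged.merge(env, on="person_id", how="inner")
    merged = merged.set_index("person_id")

    n_persons = len(merged)
    b = rng.normal(0.0, np.sqrt(config.true_tau00), size=n_persons)
    intercepts = pd.Series(b, index=merged.index, name="b")

    rows = []
    etas = []
    for pid, b_i in intercepts.items():
        eta_base = beta["intercept"] + b_i
        for term, coef in beta.items():
            if term in ("intercept", "counter"):
                continue
            if term not in merged.columns:
                raise KeyError(f"true_beta term {term!r} not found in cohort/env columns")
            eta_base += coef * float(merged.loc[pid, term])
        for counter in range(1, config.days_per_person + 1):
            eta = eta_base + beta.get("counter", 0.0) * counter
            if eta > 50:
                raise OverflowError(
                    f"linear predictor {eta:.1f} overflows exp(); reduce true_beta"
                )
            row = {"person_id": pid, "counter": counter, "eta": eta}
            rows.append(row)
            etas.append(eta)
    day = pd.DataFrame(rows)
    mu = np.exp(day.pop("eta").to_numpy())
    day["y"] = rng.poisson(mu)
    truth = SimTruth(
        beta=beta, tau00=config.true_tau00, random_intercepts=intercepts, expected_counts=mu
    )
    return day, truth


def simulate_trajectory(
    person_id: str,
    mobility_date: date,
    target_toh_min: float,
    home: HomeAnchor,
    config: SimConfig,
    seed: int | None = None,
) -> TrackDay:
    """Build one valid GPS day whose recomputed TOH matches the target.

    Fixes are emitted at ``fix_interval_s`` from 03:00 local onward over
    enough distinct hours to pass the 8-hour validity filter. A single
    out-of-home excursion of exactly ``target_toh_min`` minutes walks out
    radially (well beyond the home buffer) and back; optional isotropic GPS
    jitter (``gps_noise_sd_m``) is small relative to the buffer, so the
    recomputed indicator stays within two fix intervals of the target.
    """
    if not 0.0 <= target_toh_min <= 18 * 60:
        raise ValueError(f"target TOH must be within [0, 1080] min, got {target_toh_min}")
    interval = config.fix_interval_s
    if 0.0 < target_toh_min * 60.0 < interval:
        raise ValueError(
            f"target {target_toh_min} min is not representable at a "
            f"{interval:.0f} s fix interval"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [(config.seed if seed is None else seed) + 4_000_003,
             zlib.crc32(person_id.encode()),
             mobility_date.toordinal()]
        )
    )
    tz = ZoneInfo(config.timezone)
    day_start = datetime(
        mobility_date.year, mobility_date.month, mobility_date.day, 3, 0, tzinfo=tz
    )
    span_min = max(8 * 60 + 5, target_toh_min + 120)
    n_fix = int(span_min * 60 // interval) + 1

    excursion_start_s = 3600.0  # one hour at home before heading out
    excursion_end_s = excursion_start_s + target_toh_min * 60.0

    proj = LocalProjection(home.pos)
    theta = rng.uniform(0, 2 * np.pi)
    d_max = rng.uniform(500.0, 5000.0)
    d_min = 150.0  # always clear of the 50 m buffer, even with jitter

    fixes: list[GpsFix] = []
    for k in range(n_fix):
        t_s = k * interval
        t = day_start + timedelta(seconds=t_s)
        if target_toh_min > 0 and excursion_start_s <= t_s <= excursion_end_s:
            u = (t_s - excursion_start_s) / max(excursion_end_s - excursion_start_s, 1.0)
            dist = d_min + (d_max - d_min) * (1.0 - abs(2.0 * u - 1.0))
            x, y = dist * np.cos(theta), dist * np.sin(theta)
        else:
            x, y = 0.0, 0.0
        if config.gps_noise_sd_m > 0:
            x += rng.normal(0.0, config.gps_noise_sd_m)
            y += rng.normal(0.0, config.gps_noise_sd_m)
        pos = proj.inverse([PlanePoint(x, y)])[0]
        fixes.append(GpsFix(person_id, t, pos))

    if config.dropout_fraction > 0:
        keep = rng.random(len(fixes)) >= config.dropout_fraction
        fixes = [f for f, k in zip(fixes, keep) if k]
    return TrackDay(person_id, mobility_date, fixes)


# ---------------------------------------------------------------------------
# Writers emitting the same dialects the ingestion modules read


def write_gps_csv(fixes: Sequence[GpsFix], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "person_id": [f.person_id for f in fixes],
            "timestamp": [f.t.isoformat() for f in fixes],
            "lat": [f.pos.lat for f in fixes],
            "lon": [f.pos.lon for f in fixes],
        }
    )
    df.to_csv(path, index=False)


def write_homes_csv(homes: Mapping[str, HomeAnchor], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "person_id": list(homes),
            "lat": [h.pos.lat for h in homes.values()],
            "lon": [h.pos.lon for h in homes.values()],
            "buffer_m": [h.buffer_m for h in homes.values()],
        }
    )
    df.to_csv(path, index=False)


def write_env_geojson(
    ways: Sequence[WaySegment],
    greens: Sequence[GreenPolygon],
    pois: Sequence[PoiPoint],
    path: str | Path,
) -> None:
    features = []
    for w in ways:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[p.lon, p.lat] for p in w.polyline],
                },
                "properties": {"way_id": w.way_id, "walkable": w.walkable},
            }
        )
    for g in greens:
        rings = [[[p.lon, p.lat] for p in g.ring]]
        rings += [[[p.lon, p.lat] for p in hole] for hole in g.holes]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": rings},
                "properties": {"green_category": g.category},
            }
        )
    for poi in pois:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [poi.pos.lon, poi.pos.lat]},
                "properties": {"category": poi.category},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
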