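"""Seeded synthetic worlds, itineraries and device-faithful GPS traces.

The generator stands in for a study month: a home and a set of points of
interest inside a city-scale bounding box, a 28-day itinerary of out-of-home
visits with nightly home dwells, a travel diary that mirrors the itinerary
exactly (the ground truth), and a GPS trace rendered the way the tracked
device behaves — one fix per minute while moving, positional jitter on every
fix, and dwells that optionally collapse to their two bracketing fixes when
the device enters standby or loses signal indoors.

Density profiles: a ``sparse`` world keeps venues (and home) far apart, so
every stop has a single unambiguous candidate venue; a ``dense`` world packs
venues into plazas a few tens of metres across, which is what degrades
activity inference in highly walkable neighbourhoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np

from .activities import (
    POI,
    ActivityCategory,
    categorize_poi,
    is_open,
)
from .geo import EARTH_RADIUS_M, GeoPoint, GPSRecord, Trajectory
from .evaluation import DiaryEntry

__all__ = [
    "World",
    "ItineraryEvent",
    "DeviceModel",
    "generate_world",
    "generate_month",
    "diary_from_itinerary",
    "render_trace",
]

DEFAULT_TZ = "America/Toronto"
DEFAULT_CENTER = GeoPoint(43.70, -79.40)

#: place-type pool: mapped tokens plus a couple of types outside the mapping
#: (their ground-truth category is Other).
_TYPE_POOL = [
    "bakery", "cafe", "restaurant", "bar",
    "grocery", "supermarket",
    "clothing_store", "bookstore", "shopping_mall", "hardware_store",
    "bank", "post_office", "beauty_salon", "gas_station",
    "library", "museum", "park", "movie_theater",
    "pharmacy", "dentist", "hospital", "physiotherapist",
    "church", "synagogue",
    "gym", "ymca",
    "heliport", "embassy",
]

TRAVEL_SPEED_DRIVE_MPS = 8.0
TRAVEL_SPEED_WALK_MPS = 1.2


@dataclass
class World:
    home: GeoPoint
    pois: list[POI]
    seed: int
    bbox: tuple[float, float, float, float]  # (lat_min, lon_min, lat_max, lon_max)
    tz: str = DEFAULT_TZ

    def __post_init__(self) -> None:
        lat_min, lon_min, lat_max, lon_max = self.bbox
        for p in [self.home] + [q.location for q in self.pois]:
            if not (lat_min <= p.lat <= lat_max and lon_min <= p.lon <= lon_max):
                raise ValueError("world member outside bounding box")


@dataclass(frozen=True)
class ItineraryEvent:
    """One ground-truth dwell: at home (venue_id None) or at a POI."""

    venue_id: str | None
    location: GeoPoint
    arrival: datetime
    departure: datetime
    category: ActivityCategory


@dataclass
class DeviceModel:
    """Behaviour of the tracking device.

    One fix per ``sample_period_s`` while moving; isotropic Gaussian position
    jitter of ``jitter_sigma_m`` on every fix (real traces scatter by up to
    ~15 m, so 10 m is the default); ``standby`` suppresses all in-dwell fixes,
    otherwise each dwell independently loses signal with probability
    ``signal_loss_prob`` and then emits only its two bracketing fixes.
    """

    sample_period_s: float = 60.0
    jitter_sigma_m: float = 10.0
    standby: bool = False
    signal_loss_prob: float = 0.15
    speed_noise_mps: float = 0.2

    def __post_init__(self) -> None:
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")
        if self.jitter_sigma_m < 0:
            raise ValueError("jitter_sigma_m must be >= 0")
        if not 0.0 <= self.signal_loss_prob <= 1.0:
            raise ValueError("signal_loss_prob must be a probability")


def _offset(point: GeoPoint, dx_m: float, dy_m: float) -> GeoPoint:
    lat = point.lat + math.degrees(dy_m / EARTH_RADIUS_M)
    lon = point.lon + math.degrees(
        dx_m / (EARTH_RADIUS_M * math.cos(math.radians(point.lat)))
    )
    return GeoPoint(lat, lon)


def _local_dist(a: GeoPoint, b: GeoPoint) -> float:
    from .geo import haversine

    return haversine(a, b)


def _random_hours(rng: np.random.Generator) -> dict | None:
    if rng.random() < 0.10:
        return None  # always open
    hours = {}
    for day in ("mon", "tue", "wed", "thu", "fri", "sat", "sun"):
        if rng.random() < 0.10:
            hours[day] = []  # closed that day
        else:
            open_h = int(rng.integers(7, 10))
            close_h = int(rng.integers(17, 23))
            hours[day] = [(f"{open_h:02d}:00", f"{close_h:02d}:00")]
    return hours


def generate_world(
    seed: int,
    n_pois: int = 40,
    density_profile: str = "sparse",
    center: GeoPoint = DEFAULT_CENTER,
    half_extent_m: float = 2500.0,
) -> World:
    """Reproducible world: home at the centre, POIs placed by density profile.

    sparse: venues pairwise > 300 m apart and > 400 m from home.
    dense:  venues grouped into plazas (~5 per plaza, tens of metres apart),
            plazas well separated and away from home.
    """
    if n_pois < 0:
        raise ValueError("n_pois must be >= 0")
    if density_profile not in ("sparse", "dense"):
        raise ValueError("density_profile must be 'sparse' or 'dense'")
    rng = np.random.default_rng(seed)
    home = _offset(center, float(rng.normal(0, 20)), float(rng.normal(0, 20)))

    positions: list[tuple[float, float]] = []
    if density_profile == "sparse":
        min_sep, min_home = 320.0, 400.0
        while len(positions) < n_pois:
            x, y = rng.uniform(-half_extent_m, half_extent_m, size=2)
            if math.hypot(x, y) < min_home:
                continue
            if all(math.hypot(x - px, y - py) >= min_sep for px, py in positions):
                positions.append((float(x), float(y)))
    else:
        per_plaza = 5
        n_plazas = max(1, math.ceil(n_pois / per_plaza))
        plazas: list[tuple[float, float]] = []
        while len(plazas) < n_plazas:
            x, y = rng.uniform(-half_extent_m + 200, half_extent_m - 200, size=2)
            if math.hypot(x, y) < 500.0:
                continue
            if all(math.hypot(x - px, y - py) >= 600.0 for px, py in plazas):
                plazas.append((float(x), float(y)))
        for i in range(n_pois):
            cx, cy = plazas[i % n_plazas]
            r = float(rng.uniform(5.0, 45.0))
            th = float(rng.uniform(0, 2 * math.pi))
            positions.append((cx + r * math.cos(th), cy + r * math.sin(th)))

    pois = []
    for i, (x, y) in enumerate(positions):
        ptype = str(rng.choice(_TYPE_POOL))
        pois.append(
            POI(
                id=f"poi-{i:03d}",
                name=f"{ptype.replace('_', ' ').title()} #{i}",
                place_type=ptype,
                location=_offset(center, x, y),
                opening_hours=_random_hours(rng),
            )
        )
    margin = math.degrees((half_extent_m + 200.0) / EARTH_RADIUS_M) * 2.0
    bbox = (
        center.lat - margin,
        center.lon - margin,
        center.lat + margin,
        center.lon + margin,
    )
    return World(home=home, pois=pois, seed=seed, bbox=bbox)


def generate_month(
    world: World,
    days: int = 28,
    seed: int = 0,
    events_per_day: tuple[int, int] = (3, 6),
    start_date: tuple[int, int, int] = (2024, 4, 1),
    travel_speed_mps: float = TRAVEL_SPEED_DRIVE_MPS,
) -> list[ItineraryEvent]:
    """A ``days``-day itinerary with nightly home dwells of at least 8 hours
    and 3-6 out-of-home visits per day at venues open during the visit.

    The itinerary is the ground truth: the matching diary is produced by
    :func:`diary_from_itinerary`.
    """
    rng = np.random.default_rng(seed)
    tz = ZoneInfo(world.tz)
    y, m, d = start_date
    day0 = datetime(y, m, d, tzinfo=tz)
    events: list[ItineraryEvent] = []
    home_since = day0 + timedelta(hours=7)

    def travel_time(a: GeoPoint, b: GeoPoint) -> timedelta:
        return timedelta(seconds=max(30.0, _local_dist(a, b) / travel_speed_mps))

    for day in range(days):
        day_start = day0 + timedelta(days=day)
        depart_home = day_start + timedelta(hours=9, minutes=float(rng.uniform(0, 60)))
        cutoff = day_start + timedelta(hours=20, minutes=30)
        n_events = int(rng.integers(events_per_day[0], events_per_day[1] + 1))
        day_events: list[ItineraryEvent] = []
        cur_loc, cur_t = world.home, depart_home
        prev_venue: str | None = None
        for _ in range(n_events):
            if not world.pois:
                break
            chosen = None
            for _attempt in range(60):
                poi = world.pois[int(rng.integers(len(world.pois)))]
                if poi.id == prev_venue:
                    continue
                arr = cur_t + travel_time(cur_loc, poi.location)
                dep = arr + timedelta(minutes=float(rng.uniform(30, 90)))
                if dep > cutoff:
                    continue
                if is_open(poi, arr, dep):
                    chosen = (poi, arr, dep)
                    break
            if chosen is None:
                break
            poi, arr, dep = chosen
            day_events.append(
                ItineraryEvent(
                    venue_id=poi.id,
                    location=poi.location,
                    arrival=arr,
                    departure=dep,
                    category=categorize_poi(poi),
                )
            )
            cur_loc, cur_t, prev_venue = poi.location, dep, poi.id
        if day_events:
            # close the preceding home dwell at the morning departure
            events.append(
                ItineraryEvent(
                    venue_id=None,
                    location=world.home,
                    arrival=home_since,
                    departure=depart_home,
                    category=ActivityCategory.HOME,
                )
            )
            events.extend(day_events)
            home_since = day_events[-1].departure + travel_time(
                day_events[-1].location, world.home
            )
    # final home dwell closes the month
    end = day0 + timedelta(days=days, hours=-2)
    if end <= home_since:
        end = home_since + timedelta(hours=8)
    events.append(
        ItineraryEvent(
            venue_id=None,
            location=world.home,
            arrival=home_since,
            departure=end,
            category=ActivityCategory.HOME,
        )
    )
    return events


def diary_from_itinerary(itinerary: list[ItineraryEvent]) -> list[DiaryEntry]:
    """Ground-truth diary mirroring the itinerary exactly (coordinates, times
    and declared category), home dwells included."""
    return [
        DiaryEntry(
            arrival=e.arrival,
            departure=e.departure,
            location=e.location,
            category=e.category,
        )
        for e in itinerary
    ]


def render_trace(
    itinerary: list[ItineraryEvent],
    device: DeviceModel | None = None,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> Trajectory:
    """Render the GPS trace a tracked device would record for an itinerary.

    Dwells emit one jittered near-zero-speed fix per sample period, or only
    the two bracketing fixes when the dwell loses signal (the fix after a
    signal gap carries no speed, as devices waking from standby report none).
    Travel legs are straight lines at the implied leg speed with one fix per
    sample period.
    """
    if device is None:
        device = DeviceModel()
    if not itinerary:
        raise ValueError("itinerary is empty")
    rng = np.random.default_rng(seed)
    records: list[GPSRecord] = []
    last_t: datetime | None = None
    after_gap = False

    def jitter(p: GeoPoint) -> GeoPoint:
        dx, dy = rng.normal(0.0, device.jitter_sigma_m, size=2)
        return _offset(p, float(dx), float(dy))

    def emit(t: datetime, p: GeoPoint, v: float | None) -> None:
        nonlocal last_t, after_gap
        if last_t is not None and t <= last_t:
            return
        q = jitter(p)
        if after_gap:
            v = None  # wake-up fix: speed unknown
            after_gap = False
        records.append(GPSRecord(lat=q.lat, lon=q.lon, t=t, v=v))
        last_t = t

    period = timedelta(seconds=device.sample_period_s)
    for idx, ev in enumerate(itinerary):
        lost = device.standby or (rng.random() < device.signal_loss_prob)
        dwell_v = lambda: abs(float(rng.normal(0.0, device.speed_noise_mps)))
        if lost:
            emit(ev.arrival, ev.location, dwell_v())
            after_gap = True  # the departure fix wakes the device: no speed
            emit(ev.departure, ev.location, dwell_v())
        else:
            t = ev.arrival
            while t <= ev.departure:
                emit(t, ev.location, dwell_v())
                t += period
            if last_t is not None and last_t < ev.departure:
                emit(ev.departure, ev.location, dwell_v())
        # travel to the next event
        if idx + 1 < len(itinerary):
            nxt = itinerary[idx + 1]
            leg = (nxt.arrival - ev.departure).total_seconds()
            if leg > 0:
                dist = _local_dist(ev.location, nxt.location)
                speed = dist / leg
                t = ev.departure + period
                while t < nxt.arrival:
                    f = (t - ev.departure).total_seconds() / leg
                    pos = GeoPoint(
                        ev.location.lat + f * (nxt.location.lat - ev.location.lat),
                        ev.location.lon + f * (nxt.location.lon - ev.location.lon),
                    )
                    v = max(0.0, speed + float(rng.normal(0.0, device.speed_noise_mps)))
                    emit(t, pos, v)
                    t += period
    return Trajectory(subject_id=subject_id, records=records)
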