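from __future__ import annotations

from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import pytest

import lifespace as ls
from lifespace.simulate import (
    DeviceModel,
    diary_from_itinerary,
    generate_month,
    generate_world,
    render_trace,
)

TZ = ZoneInfo("America/Toronto")
BASE = datetime(2024, 3, 4, 8, 0, tzinfo=TZ)


def rec(lat: float, lon: float, minutes: float, v: float | None = 0.0) -> ls.GPSRecord:
    """A fix ``minutes`` after the common base time."""
    return ls.GPSRecord(lat=lat, lon=lon, t=BASE + timedelta(minutes=minutes), v=v)


def run_month(
    seed: int,
    profile: str = "sparse",
    days: int = 28,
    jitter_m: float = 10.0,
    n_pois: int = 40,
) -> dict:
    """End-to-end pipeline on one seeded synthetic month; returns the metrics
    a study would report for that subject."""
    world = generate_world(seed * 100 + 1, n_pois=n_pois, density_profile=profile)
    itinerary = generate_month(world, days=days, seed=seed * 100 + 2)
    device = DeviceModel(jitter_sigma_m=jitter_m)
    traj = render_trace(itinerary, device, seed=seed * 100 + 3)
    stops = ls.detect_stops(traj)
    diary = diary_from_itinerary(itinerary)
    counts, pairs = ls.match_stops(stops, diary)
    home = ls.infer_home(stops)
    annotated, _ = ls.annotate_all(stops, home, ls.POIStore(world.pois))
    act = ls.activity_f1(annotated, diary, pairs)
    return {
        "world": world,
        "stops": stops,
        "diary": diary,
        "pairs": pairs,
        "annotated": annotated,
        "stop_f1": ls.compute_f1(counts).f1,
        "activity_f1": act.global_metrics.f1,
        "home_error_m": ls.home_error(home, world.home),
        "home": home,
    }


@pytest.fixture(scope="session")
def sparse_month() -> dict:
    """One full synthetic month, reused across tests that only read it."""
    return run_month(seed=7)
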