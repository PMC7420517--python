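"""Activity-type inference for stops.

Each out-of-home stop is annotated by (1) collecting the points of interest
within a search radius (default 150 m) of the stop centroid, (2) keeping only
the POIs that were open during the stop interval, (3) mapping POI place types
to one of eight activity categories, and (4) scoring each category with a
gravity-law weight: every open POI contributes 1/(d + eps)^2 of mass to its
category, so both proximity and local prevalence raise a category's
probability. Stops within the home radius are labelled Home outright; stops
with no candidate POIs fall back to Other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from enum import Enum

import numpy as np

from .geo import GeoPoint, haversine, haversine_arrays
from .home import HomeEstimate
from .stops import Stop, StopList

__all__ = [
    "ActivityCategory",
    "CATEGORY_ORDER",
    "PLACE_TYPE_MAP",
    "POI",
    "POIStore",
    "GravityParams",
    "ActivityDistribution",
    "AnnotatedStop",
    "normalize_place_type",
    "map_place_type",
    "categorize_poi",
    "nearby_pois",
    "is_open",
    "gravity_distribution",
    "infer_activity",
    "annotate_all",
]


class ActivityCategory(str, Enum):
    FOOD = "Food"
    DAILY_SHOPPING = "DailyShopping"
    SHOPPING = "Shopping"
    SERVICES = "Services"
    LEISURE = "Leisure"
    MEDICAL_SERVICES = "MedicalServices"
    RELIGIOUS = "Religious"
    SPORT = "Sport"
    HOME = "Home"
    OTHER = "Other"


#: Deterministic tie-break order for argmax: the eight out-of-home categories
#: in their canonical table order, then Home, then Other.
CATEGORY_ORDER: list[ActivityCategory] = list(ActivityCategory)

_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}

_RAW_MAP: dict[ActivityCategory, list[str]] = {
    ActivityCategory.FOOD: [
        "bakery", "bar", "cafe", "food", "meal_takeaway", "restaurant",
        "meal_delivery",
    ],
    ActivityCategory.DAILY_SHOPPING: ["grocery", "supermarket"],
    ActivityCategory.SHOPPING: [
        "bookstore", "clothing_store", "convenience_store", "hardware_store",
        "electronics_store", "furniture_store", "shopping_mall", "liquor_store",
        "pet_store", "shoe_store", "department_store",
    ],
    ActivityCategory.SERVICES: [
        "atm", "bank", "car_rental", "car_repair", "finance", "insurance",
        "gas_station", "travel_agency", "post_office", "accounting",
        "beauty_salon", "courthouse", "laundry",
    ],
    ActivityCategory.LEISURE: [
        "bowling_alley", "casino", "library", "movie_rental", "movie_theater",
        "museum", "park", "spa", "stadium", "lodging",
    ],
    ActivityCategory.MEDICAL_SERVICES: [
        "dentist", "hospital", "pharmacy", "physiotherapist", "chiropractor",
        "psychologist", "naturopath", "walk_in_clinic", "sleep_lab",
    ],
    ActivityCategory.RELIGIOUS: ["church", "hindu_temple", "synagogue", "mosque"],
    ActivityCategory.SPORT: ["gym", "ymca"],
}

PLACE_TYPE_MAP: dict[str, ActivityCategory] = {
    t: cat for cat, types in _RAW_MAP.items() for t in types
}

#: Brand names (medical laboratory chains) matched on the POI *name*, not the
#: place type; any POI whose name contains one maps to MedicalServices.
MEDICAL_NAME_BRANDS = ("lifelabs", "dynacare")

_WEEKDAYS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")


def normalize_place_type(place_type: str) -> str:
    return place_type.strip().lower().replace(" ", "_").replace("-", "_")


def map_place_type(place_type: str) -> ActivityCategory:
    """Exact dictionary lookup of a place-type token; unknown types → Other."""
    return PLACE_TYPE_MAP.get(normalize_place_type(place_type), ActivityCategory.OTHER)


OpeningHours = dict[str, list[tuple[str, str]]]


@dataclass(frozen=True)
class POI:
    """A named place with a type token and weekly opening hours.

    ``opening_hours`` maps weekday keys (mon..sun) to lists of [open, close)
    "HH:MM" intervals in local wall time. An empty list means closed that day;
    ``None`` for the whole field means always open.
    """

    id: str
    name: str
    place_type: str
    location: GeoPoint
    opening_hours: OpeningHours | None = None

    def __post_init__(self) -> None:
        if self.opening_hours is None:
            return
        for day, intervals in self.opening_hours.items():
            if day not in _WEEKDAYS:
                raise ValueError(f"unknown weekday key {day!r}")
            parsed = sorted((_parse_hhmm(o), _parse_hhmm(c)) for o, c in intervals)
            for o, c in parsed:
                if not o < c:
                    raise ValueError(f"opening interval must have open < close ({day})")
            for (_, c1), (o2, _) in zip(parsed, parsed[1:]):
                if o2 < c1:
                    raise ValueError(f"overlapping opening intervals on {day}")


def categorize_poi(poi: POI) -> ActivityCategory:
    name = poi.name.lower()
    if any(brand in name for brand in MEDICAL_NAME_BRANDS):
        return ActivityCategory.MEDICAL_SERVICES
    return map_place_type(poi.place_type)


class POIStore:
    """In-memory POI collection supporting radius queries."""

    def __init__(self, pois: list[POI]):
        self.pois = list(pois)
        self._lat = np.array([p.location.lat for p in self.pois], dtype=float)
        self._lon = np.array([p.location.lon for p in self.pois], dtype=float)

    def __len__(self) -> int:
        return len(self.pois)

    def __iter__(self):
        return iter(self.pois)

    def query(self, point: GeoPoint, radius_m: float) -> list[tuple[POI, float]]:
        """POIs strictly within ``radius_m`` of ``point``, nearest first;
        distance ties are broken by POI id."""
        if not self.pois:
            return []
        d = haversine_arrays(
            np.asarray(point.lat), np.asarray(point.lon), self._lat, self._lon
        )
        idx = np.flatnonzero(d < radius_m)
        hits = [(self.pois[i], float(d[i])) for i in idx]
        hits.sort(key=lambda h: (h[1], h[0].id))
        return hits


def nearby_pois(store: POIStore, stop: Stop, radius_m: float) -> list[tuple[POI, float]]:
    """Radius query around the stop centroid (strict ``<`` at the boundary)."""
    return store.query(stop.location, radius_m)


def _parse_hhmm(s: str) -> time:
    h, m = s.split(":")
    return time(int(h), int(m))


def is_open(poi: POI, start: datetime, end: datetime) -> bool:
    """True iff [start, end] overlaps an opening interval on any day it touches.

    Opening hours are interpreted in the wall-clock timezone of ``start``.
    A POI without opening hours is always open.
    """
    if start > end:
        raise ValueError("interval start after end")
    if poi.opening_hours is None:
        return True
    tz = start.tzinfo
    day = start.date()
    while day <= end.date():
        intervals = poi.opening_hours.get(_WEEKDAYS[day.weekday()], [])
        for o, c in intervals:
            abs_open = datetime.combine(day, _parse_hhmm(o), tzinfo=tz)
            abs_close = datetime.combine(day, _parse_hhmm(c), tzinfo=tz)
            if abs_open < end and start < abs_close:
                return True
        day = day + timedelta(days=1)
    return False


@dataclass
class GravityParams:
    """search_radius_m: POI lookup radius around each stop; exponent/epsilon_d_m:
    gravity weight 1/(d + epsilon_d)^exponent; home_radius_m: distance from the
    inferred home within which a stop is labelled Home (None → use the DBSCAN
    Eps of the home estimate, falling back to 150 m)."""

    search_radius_m: float = 150.0
    exponent: float = 2.0
    epsilon_d_m: float = 1.0
    home_radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.search_radius_m <= 0 or self.exponent <= 0:
            raise ValueError("search_radius_m and exponent must be positive")
        if self.epsilon_d_m < 0:
            raise ValueError("epsilon_d_m must be >= 0")


@dataclass
class ActivityDistribution:
    """A probability over activity categories plus its argmax label."""

    probs: dict[ActivityCategory, float]
    label: ActivityCategory
    candidate_count: int


def _argmax_category(scores: dict[ActivityCategory, float]) -> ActivityCategory:
    return max(scores, key=lambda c: (scores[c], -_CATEGORY_RANK[c]))


def gravity_distribution(
    stop: Stop, open_pois: list[tuple[POI, float]], gp: GravityParams
) -> ActivityDistribution:
    """Gravity-law category distribution over the stop's open POIs.

    Each POI contributes weight 1/(d + epsilon)^exponent to its category;
    category scores are normalised to probabilities. With no candidates the
    distribution degenerates to Other = 1.
    """
    if not open_pois:
        return ActivityDistribution(
            probs={ActivityCategory.OTHER: 1.0},
            label=ActivityCategory.OTHER,
            candidate_count=0,
        )
    scores: dict[ActivityCategory, float] = {}
    for poi, d in open_pois:
        w = 1.0 / (d + gp.epsilon_d_m) ** gp.exponent
        cat = categorize_poi(poi)
        scores[cat] = scores.get(cat, 0.0) + w
    total = sum(scores.values())
    probs = {c: s / total for c, s in scores.items()}
    return ActivityDistribution(
        probs=probs, label=_argmax_category(probs), candidate_count=len(open_pois)
    )


@dataclass
class AnnotatedStop:
    stop: Stop
    distribution: ActivityDistribution
    is_home: bool = False

    def __post_init__(self) -> None:
        if self.is_home and self.distribution.label is not ActivityCategory.HOME:
            raise ValueError("is_home stop must carry the Home label")

    @property
    def label(self) -> ActivityCategory:
        return self.distribution.label


def _home_radius(home: HomeEstimate | None, gp: GravityParams) -> float:
    if gp.home_radius_m is not None:
        return gp.home_radius_m
    if home is not None and home.eps_used_m > 0:
        return home.eps_used_m
    return 150.0


def infer_activity(
    stop: Stop,
    home: HomeEstimate | None,
    store: POIStore,
    gp: GravityParams | None = None,
) -> AnnotatedStop:
    """Label one stop: Home if within the home radius, else the gravity argmax
    over nearby open POIs, else Other."""
    if gp is None:
        gp = GravityParams()
    if home is not None and haversine(stop.location, home.location) < _home_radius(home, gp):
        dist = ActivityDistribution(
            probs={ActivityCategory.HOME: 1.0},
            label=ActivityCategory.HOME,
            candidate_count=0,
        )
        return AnnotatedStop(stop=stop, distribution=dist, is_home=True)
    candidates = nearby_pois(store, stop, gp.search_radius_m)
    open_candidates = [(p, d) for p, d in candidates if is_open(p, stop.start, stop.end)]
    return AnnotatedStop(
        stop=stop, distribution=gravity_distribution(stop, open_candidates, gp)
    )


def annotate_all(
    stops: StopList,
    home: HomeEstimate | None,
    store: POIStore,
    gp: GravityParams | None = None,
) -> tuple[list[AnnotatedStop], dict[ActivityCategory, float]]:
    """Annotate every stop and tabulate the per-category percentage of stops."""
    annotated = [infer_activity(s, home, store, gp) for s in stops.stops]
    freq: dict[ActivityCategory, float] = {}
    if annotated:
        for a in annotated:
            freq[a.label] = freq.get(a.label, 0.0) + 1.0
        freq = {c: 100.0 * n / len(annotated) for c, n in freq.items()}
    return annotated, freq
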