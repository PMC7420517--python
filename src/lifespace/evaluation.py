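"""Validation of extracted stops and inferred activities against a travel diary.

A diary entry matches an extracted stop when the two overlap in time and lie
within 150 m of each other; matching is one-to-one and greedy in ascending
distance. Matched pairs are true positives, unmatched diary entries false
negatives, unmatched extracted stops false positives. True negatives ("no
stop extracted or recorded") are ill-posed on continuous time and never enter
precision/recall/F1; they are reported as 0 unless a caller supplies a count.

Also provided: activity agreement scoring over the matched pairs (per-category
one-vs-rest and global micro-average F1), home-location error, the life-space
convex-hull envelope, and Walk Score bucketing of out-of-home destinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from shapely.geometry import MultiPoint

from .activities import ActivityCategory, AnnotatedStop
from .geo import GeoPoint, haversine, local_project, local_unproject
from .home import HomeEstimate
from .stops import Stop, StopList

__all__ = [
    "DiaryEntry",
    "ConfusionCounts",
    "EvalMetrics",
    "MatchedPair",
    "match_stops",
    "compute_f1",
    "activity_f1",
    "home_error",
    "LifeSpaceEnvelope",
    "life_space_envelope",
    "WALK_SCORE_BUCKETS",
    "bucket_walk_score",
    "WalkScoreTable",
    "per_bucket_f1",
]


@dataclass(frozen=True)
class DiaryEntry:
    """One participant-recorded excursion (or at-home interval): arrival,
    departure, destination coordinates and the declared activity category."""

    arrival: datetime
    departure: datetime
    location: GeoPoint
    category: ActivityCategory

    def __post_init__(self) -> None:
        if not self.departure > self.arrival:
            raise ValueError("diary departure must be after arrival")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvalMetrics:
    """precision/recall/f1 in [0,1], or None where the ratio is undefined
    (no predicted positives, no actual positives, or p + r = 0)."""

    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class MatchedPair:
    stop_index: int
    diary_index: int
    distance_m: float


def _overlaps(stop: Stop, entry: DiaryEntry) -> bool:
    return stop.start <= entry.departure and entry.arrival <= stop.end


def match_stops(
    extracted: StopList,
    recorded: list[DiaryEntry],
    match_radius_m: float = 150.0,
    require_temporal_overlap: bool = True,
    tn: int = 0,
) -> tuple[ConfusionCounts, list[MatchedPair]]:
    """Greedy one-to-one matching of extracted stops to diary entries.

    Candidate pairs must lie strictly within ``match_radius_m`` and (by
    default) overlap in time; pairs are consumed in ascending distance.
    """
    stops = extracted.stops
    candidates: list[tuple[float, int, int]] = []
    for i, s in enumerate(stops):
        for j, e in enumerate(recorded):
            if require_temporal_overlap and not _overlaps(s, e):
                continue
            d = haversine(s.location, e.location)
            if d < match_radius_m:
                candidates.append((d, i, j))
    candidates.sort()
    used_s: set[int] = set()
    used_e: set[int] = set()
    pairs: list[MatchedPair] = []
    for d, i, j in candidates:
        if i in used_s or j in used_e:
            continue
        used_s.add(i)
        used_e.add(j)
        pairs.append(MatchedPair(stop_index=i, diary_index=j, distance_m=d))
    counts = ConfusionCounts(
        tp=len(pairs),
        fp=len(stops) - len(pairs),
        fn=len(recorded) - len(pairs),
        tn=tn,
    )
    return counts, pairs


def compute_f1(counts: ConfusionCounts) -> EvalMetrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2pr/(p+r); any undefined
    ratio is reported as None, never silently 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    if p is None or r is None or p + r == 0:
        f = None
    else:
        f = 2.0 * p * r / (p + r)
    return EvalMetrics(precision=p, recall=r, f1=f)


@dataclass
class ActivityEvaluation:
    global_metrics: EvalMetrics
    per_category: dict[ActivityCategory, EvalMetrics]
    declared_pct: dict[ActivityCategory, float]
    inferred_pct: dict[ActivityCategory, float]


def activity_f1(
    annotated: list[AnnotatedStop],
    diary: list[DiaryEntry],
    pairs: list[MatchedPair],
) -> ActivityEvaluation:
    """Score inferred labels against declared categories over matched (TP)
    stops only: per-category one-vs-rest F1 and a global micro-average."""
    import warnings

    if not pairs:
        warnings.warn("no matched stops; activity agreement undefined", stacklevel=2)
        return ActivityEvaluation(
            global_metrics=EvalMetrics(None, None, None),
            per_category={},
            declared_pct={},
            inferred_pct={},
        )
    y_true = [diary[p.diary_index].category for p in pairs]
    y_pred = [annotated[p.stop_index].label for p in pairs]
    n = len(pairs)
    cats = sorted(set(y_true) | set(y_pred), key=list(ActivityCategory).index)
    per: dict[ActivityCategory, EvalMetrics] = {}
    micro_tp = 0
    for c in cats:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        per[c] = compute_f1(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        micro_tp += tp
    # micro-average over single-label pairs: FP total == FN total, so
    # precision = recall = accuracy
    acc = micro_tp / n
    declared = {c: 100.0 * y_true.count(c) / n for c in set(y_true)}
    inferred = {c: 100.0 * y_pred.count(c) / n for c in set(y_pred)}
    return ActivityEvaluation(
        global_metrics=EvalMetrics(precision=acc, recall=acc, f1=acc),
        per_category=per,
        declared_pct=declared,
        inferred_pct=inferred,
    )


def home_error(estimate: HomeEstimate, truth: GeoPoint) -> float:
    """Great-circle distance (m) between the inferred and actual home."""
    return haversine(estimate.location, truth)


@dataclass
class LifeSpaceEnvelope:
    """Convex hull of all stop centroids — the extent of travel into the
    environment — with its area in square metres."""

    hull: list[GeoPoint]
    area_m2: float


def life_space_envelope(stops: StopList) -> LifeSpaceEnvelope:
    """Convex hull of stop centroids in a local planar projection.

    Degenerate inputs (fewer than 3 distinct or collinear points) yield area 0
    with the distinct points as the "hull".
    """
    pts = stops.centroids()
    if not pts:
        raise ValueError("life-space envelope needs at least one stop")
    origin = GeoPoint(
        sum(p.lat for p in pts) / len(pts), sum(p.lon for p in pts) / len(pts)
    )
    xy = local_project(pts, origin)
    hull_geom = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull_geom.geom_type == "Polygon":
        coords = list(hull_geom.exterior.coords)[:-1]
        return LifeSpaceEnvelope(
            hull=local_unproject(np.array(coords), origin),
            area_m2=float(hull_geom.area),
        )
    # point or line: keep distinct points, zero area
    distinct = sorted({(round(x, 6), round(y, 6)) for x, y in xy})
    return LifeSpaceEnvelope(
        hull=local_unproject(np.array(distinct), origin), area_m2=0.0
    )


#: Walk Score bucket names with their closed integer ranges; the ranges
#: partition [0, 100].
WALK_SCORE_BUCKETS: list[tuple[str, int, int]] = [
    ("Walker's Paradise", 90, 100),
    ("Very Walkable", 70, 89),
    ("Somewhat Walkable", 50, 69),
    ("Car-Dependent", 25, 49),
    ("Very Car-Dependent", 0, 24),
]


def bucket_walk_score(score: int) -> str:
    if not 0 <= score <= 100:
        raise ValueError(f"Walk Score must be in [0, 100], got {score!r}")
    for name, lo, hi in WALK_SCORE_BUCKETS:
        if lo <= score <= hi:
            return name
    raise AssertionError("unreachable: buckets partition [0, 100]")


class WalkScoreTable:
    """Per-destination Walk Score values, looked up by nearest coordinate.

    Scores are an external input (from the Walk Score service); they are never
    computed here.
    """

    def __init__(self, rows: list[tuple[GeoPoint, int]]):
        for _, s in rows:
            if not 0 <= s <= 100:
                raise ValueError(f"Walk Score must be in [0, 100], got {s!r}")
        self.rows = rows

    def lookup(self, point: GeoPoint, max_distance_m: float = 150.0) -> int | None:
        best: tuple[float, int] | None = None
        for loc, score in self.rows:
            d = haversine(point, loc)
            if d < max_distance_m and (best is None or d < best[0]):
                best = (d, score)
        return None if best is None else best[1]


def per_bucket_f1(
    annotated: list[AnnotatedStop],
    diary: list[DiaryEntry],
    pairs: list[MatchedPair],
    scores: WalkScoreTable,
) -> list[dict]:
    """Activity micro-F1 of out-of-home matched stops, grouped by the Walk
    Score bucket of the destination. Destinations without a score are skipped."""
    grouped: dict[str, list[MatchedPair]] = {}
    for p in pairs:
        entry = diary[p.diary_index]
        if entry.category is ActivityCategory.HOME:
            continue
        score = scores.lookup(entry.location)
        if score is None:
            continue
        grouped.setdefault(bucket_walk_score(score), []).append(p)
    out = []
    for name, lo, hi in WALK_SCORE_BUCKETS:
        bucket_pairs = grouped.get(name, [])
        if not bucket_pairs:
            continue
        agree = sum(
            1
            for p in bucket_pairs
            if annotated[p.stop_index].label == diary[p.diary_index].category
        )
        out.append(
            {
                "bucket": name,
                "range": [lo, hi],
                "n_stops": len(bucket_pairs),
                "f1": agree / len(bucket_pairs),
            }
        )
    return out
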