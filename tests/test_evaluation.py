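from __future__ import annotations

import math
from datetime import timedelta

import numpy as np
import pytest

from lifespace.activities import ActivityCategory, ActivityDistribution, AnnotatedStop
from lifespace.evaluation import (
    WALK_SCORE_BUCKETS,
    ConfusionCounts,
    DiaryEntry,
    WalkScoreTable,
    activity_f1,
    bucket_walk_score,
    compute_f1,
    home_error,
    life_space_envelope,
    match_stops,
    per_bucket_f1,
)
from lifespace.geo import EARTH_RADIUS_M, GeoPoint, local_project
from lifespace.home import HomeEstimate
from lifespace.stops import Stop, StopKind, StopList

from _oracles import brute_hull_vertices
from conftest import BASE


def lon_m(meters: float, lat: float = 0.0) -> float:
    return math.degrees(meters / (EARTH_RADIUS_M * math.cos(math.radians(lat))))


def stop(lon_off_m: float, start_min: float, end_min: float) -> Stop:
    return Stop(
        location=GeoPoint(0.0, lon_m(lon_off_m)),
        start=BASE + timedelta(minutes=start_min),
        end=BASE + timedelta(minutes=end_min),
        kind=StopKind.FULL_SIGNAL,
        member_count=5,
    )


def entry(
    lon_off_m: float,
    start_min: float,
    end_min: float,
    cat: ActivityCategory = ActivityCategory.FOOD,
) -> DiaryEntry:
    return DiaryEntry(
        arrival=BASE + timedelta(minutes=start_min),
        departure=BASE + timedelta(minutes=end_min),
        location=GeoPoint(0.0, lon_m(lon_off_m)),
        category=cat,
    )


def annotated(s: Stop, cat: ActivityCategory) -> AnnotatedStop:
    return AnnotatedStop(
        stop=s,
        distribution=ActivityDistribution(probs={cat: 1.0}, label=cat, candidate_count=1),
        is_home=cat is ActivityCategory.HOME,
    )


class TestMatchStops:
    def test_overlapping_nearby_pair_is_tp(self):
        counts, pairs = match_stops(
            StopList("s", [stop(100, 0, 30)]), [entry(0, 5, 25)]
        )
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert pairs[0].distance_m == pytest.approx(100, abs=0.1)

    def test_beyond_radius_is_fp_and_fn(self):
        counts, pairs = match_stops(
            StopList("s", [stop(200, 0, 30)]), [entry(0, 5, 25)]
        )
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)
        assert pairs == []

    def test_no_temporal_overlap_no_match(self):
        counts, _ = match_stops(
            StopList("s", [stop(0, 0, 30)]), [entry(0, 60, 90)]
        )
        assert counts.tp == 0
        counts, _ = match_stops(
            StopList("s", [stop(0, 0, 30)]),
            [entry(0, 60, 90)],
            require_temporal_overlap=False,
        )
        assert counts.tp == 1

    def test_empty_extraction_all_fn(self):
        counts, _ = match_stops(
            StopList("s", []), [entry(0, 0, 30), entry(300, 40, 60), entry(600, 70, 90)]
        )
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_greedy_prefers_nearest(self):
        stops = StopList("s", [stop(0, 0, 30), stop(40, 35, 60)])
        diary = [entry(10, 0, 60)]
        _, pairs = match_stops(stops, diary)
        assert len(pairs) == 1 and pairs[0].stop_index == 0

    def test_count_identities(self):
        rng = np.random.default_rng(41)
        stops, diary = [], []
        t = 0.0
        for i in range(12):
            t += 40
            stops.append(stop(float(rng.uniform(0, 2000)), t, t + 30))
            diary.append(entry(float(rng.uniform(0, 2000)), t, t + 30))
        counts, _ = match_stops(StopList("s", stops), diary)
        assert counts.tp + counts.fn == len(diary)
        assert counts.tp + counts.fp == len(stops)

    def test_infinite_radius_full_overlap_saturates(self):
        # every stop overlaps every diary entry; with an unbounded radius the
        # greedy matcher saturates the smaller list
        stops = StopList("s", [stop(i * 500, i * 70, i * 70 + 60) for i in range(3)])
        diary = [entry(i * 700, 0, 300) for i in range(5)]
        counts, _ = match_stops(stops, diary, match_radius_m=float("inf"))
        assert counts.tp == min(len(stops.stops), len(diary))


class TestF1:
    def test_perfect(self):
        m = compute_f1(ConfusionCounts(tp=10))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        m = compute_f1(ConfusionCounts(tp=7, fp=1, fn=3))
        assert m.precision == pytest.approx(0.875)
        assert m.recall == pytest.approx(0.7)
        assert m.f1 == pytest.approx(0.7778, abs=1e-4)

    def test_degenerate_is_undefined_not_zero(self):
        m = compute_f1(ConfusionCounts())
        assert m.precision is None and m.recall is None and m.f1 is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestActivityF1:
    def _pairs(self, n):
        from lifespace.evaluation import MatchedPair

        return [MatchedPair(i, i, 10.0) for i in range(n)]

    def test_full_agreement(self):
        stops = [stop(i * 500, i * 60, i * 60 + 30) for i in range(20)]
        ann = [annotated(s, ActivityCategory.FOOD) for s in stops]
        diary = [entry(i * 500, i * 60, i * 60 + 30) for i in range(20)]
        res = activity_f1(ann, diary, self._pairs(20))
        assert res.global_metrics.f1 == 1.0

    def test_partial_confusion_table(self):
        # 10 declared Food; 8 inferred Food, 2 inferred Shopping
        stops = [stop(i * 500, i * 60, i * 60 + 30) for i in range(10)]
        labels = [ActivityCategory.FOOD] * 8 + [ActivityCategory.SHOPPING] * 2
        ann = [annotated(s, lab) for s, lab in zip(stops, labels)]
        diary = [entry(i * 500, i * 60, i * 60 + 30) for i in range(10)]
        res = activity_f1(ann, diary, self._pairs(10))
        assert res.global_metrics.f1 == pytest.approx(0.8)
        assert res.per_category[ActivityCategory.FOOD].recall == pytest.approx(0.8)
        assert res.per_category[ActivityCategory.FOOD].precision == 1.0
        assert res.per_category[ActivityCategory.SHOPPING].precision == 0.0

    def test_no_pairs_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="no matched stops"):
            res = activity_f1([], [], [])
        assert res.global_metrics.f1 is None


class TestHomeError:
    def test_identical_points(self):
        est = HomeEstimate(GeoPoint(43.7, -79.4), 50.0, 10, 1e5)
        assert home_error(est, GeoPoint(43.7, -79.4)) == 0.0

    def test_millidegree_east_at_equator(self):
        est = HomeEstimate(GeoPoint(0.0, 0.001), 50.0, 10, 1e5)
        assert home_error(est, GeoPoint(0.0, 0.0)) == pytest.approx(111.195, abs=0.01)

    def test_synthetic_month(self, sparse_month):
        assert sparse_month["home_error_m"] < 50.0


class TestLifeSpace:
    def test_square_kilometre(self):
        side = 1000.0
        pts = [(0.0, 0.0), (side, 0.0), (side, side), (0.0, side)]
        stops = [
            Stop(
                location=GeoPoint(
                    43.7 + math.degrees(y / EARTH_RADIUS_M),
                    -79.4 + lon_m(x, 43.7),
                ),
                start=BASE + timedelta(minutes=40 * i),
                end=BASE + timedelta(minutes=40 * i + 30),
                kind=StopKind.FULL_SIGNAL,
            )
            for i, (x, y) in enumerate(pts)
        ]
        env = life_space_envelope(StopList("s", stops))
        assert env.area_m2 == pytest.approx(1.0e6, rel=0.005)
        assert len(env.hull) == 4

    def test_collinear_stops_zero_area(self):
        stops = [stop(i * 300, i * 60, i * 60 + 30) for i in range(3)]
        env = life_space_envelope(StopList("s", stops))
        assert env.area_m2 == 0.0

    def test_hull_matches_half_plane_oracle(self):
        rng = np.random.default_rng(43)
        stops = []
        for i in range(100):
            stops.append(
                Stop(
                    location=GeoPoint(
                        43.7 + float(rng.uniform(-0.02, 0.02)),
                        -79.4 + float(rng.uniform(-0.02, 0.02)),
                    ),
                    start=BASE + timedelta(minutes=40 * i),
                    end=BASE + timedelta(minutes=40 * i + 30),
                    kind=StopKind.FULL_SIGNAL,
                )
            )
        sl = StopList("s", stops)
        env = life_space_envelope(sl)
        pts = sl.centroids()
        origin = GeoPoint(
            sum(p.lat for p in pts) / len(pts), sum(p.lon for p in pts) / len(pts)
        )
        xy = local_project(pts, origin)
        want = brute_hull_vertices(xy)
        got = {tuple(np.round(p, 6)) for p in local_project(env.hull, origin)}
        want_rounded = {tuple(np.round(p, 6)) for p in want}
        assert got == want_rounded


class TestWalkScore:
    @pytest.mark.parametrize(
        "score,bucket",
        [
            (94, "Walker's Paradise"),
            (90, "Walker's Paradise"),
            (89, "Very Walkable"),
            (65, "Somewhat Walkable"),
            (49, "Car-Dependent"),
            (24, "Very Car-Dependent"),
            (0, "Very Car-Dependent"),
        ],
    )
    def test_bucketing(self, score, bucket):
        assert bucket_walk_score(score) == bucket

    def test_out_of_range_rejected(self):
        for bad in (-1, 101):
            with pytest.raises(ValueError):
                bucket_walk_score(bad)

    def test_ranges_partition_0_100(self):
        covered = sorted(
            s for _, lo, hi in WALK_SCORE_BUCKETS for s in range(lo, hi + 1)
        )
        assert covered == list(range(101))

    def test_per_bucket_f1(self):
        from lifespace.evaluation import MatchedPair

        stops = [stop(i * 1000, i * 60, i * 60 + 30) for i in range(4)]
        labels = [
            ActivityCategory.FOOD,
            ActivityCategory.FOOD,
            ActivityCategory.SPORT,
            ActivityCategory.HOME,
        ]
        declared = [
            ActivityCategory.FOOD,
            ActivityCategory.SHOPPING,
            ActivityCategory.SPORT,
            ActivityCategory.HOME,
        ]
        ann = [annotated(s, lab) for s, lab in zip(stops, labels)]
        diary = [
            entry(i * 1000, i * 60, i * 60 + 30, cat) for i, cat in enumerate(declared)
        ]
        pairs = [MatchedPair(i, i, 5.0) for i in range(4)]
        table = WalkScoreTable(
            [(GeoPoint(0.0, lon_m(i * 1000)), s) for i, s in enumerate([95, 95, 30, 95])]
        )
        rows = per_bucket_f1(ann, diary, pairs, table)
        by_name = {r["bucket"]: r for r in rows}
        # home stop excluded; two Walker's Paradise stops, one agreeing
        assert by_name["Walker's Paradise"]["n_stops"] == 2
        assert by_name["Walker's Paradise"]["f1"] == pytest.approx(0.5)
        assert by_name["Car-Dependent"]["f1"] == 1.0
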