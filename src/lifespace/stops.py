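"""Stop extraction from a GPS trajectory.

Two stop types are recognised. A *full-signal* stop is a run of consecutive
fixes that stay close in time and space at low speed — the device kept
reporting while the subject dwelt. A *no-signal* stop is inferred from a long
time gap between two nearby fixes: either the sky view was obstructed or the
device entered standby because no motion was detected. Adjacent candidate
clusters closer than the distance threshold and separated by less than the
time threshold are merged into one stop.

All threshold comparisons (gap, distance, speed) use strict ``<``; the dwell
filter uses ``>=`` (a stop is a place where the subject stays at least the
minimum dwell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

import numpy as np

from .geo import GeoPoint, StopParams, Trajectory, centroid, haversine

__all__ = [
    "StopKind",
    "Stop",
    "StopList",
    "detect_full_signal",
    "detect_no_signal",
    "merge_adjacent",
    "detect_stops",
]


class StopKind(str, Enum):
    FULL_SIGNAL = "full_signal"
    NO_SIGNAL = "no_signal"
    MERGED = "merged"


@dataclass(frozen=True)
class Stop:
    """A dwell episode: centroid location, time interval and provenance."""

    location: GeoPoint
    start: datetime
    end: datetime
    kind: StopKind
    member_count: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("stop end precedes start")
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")

    @property
    def dwell_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class StopList:
    """Chronological, non-overlapping stops for one subject."""

    subject_id: str
    stops: list[Stop] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.stops, self.stops[1:]):
            if b.start < a.end:
                raise ValueError("stops overlap in time")

    def __len__(self) -> int:
        return len(self.stops)

    def centroids(self) -> list[GeoPoint]:
        return [s.location for s in self.stops]


def _speed_ok(v: np.ndarray, p: StopParams) -> np.ndarray:
    absent = np.isnan(v)
    ok = v < p.delta_v_mps
    ok[absent] = not p.strict_speed
    return ok


def detect_full_signal(traj: Trajectory, p: StopParams) -> list[Stop]:
    """Single-pass clustering of consecutive low-speed, nearby fixes.

    A fix joins the open cluster iff its gap to the previous fix is < gap_t,
    its distance to the previous fix is < delta_d and its speed passes the
    speed test; otherwise the open cluster closes (emitted if its dwell is
    >= min_dwell) and the breaking fix seeds the next cluster.
    """
    lat, lon, t, v = traj.arrays()
    n = len(t)
    if n == 1:
        return []
    from .geo import haversine_arrays

    dt = np.diff(t)
    dist = haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    joins = (dt < p.gap_t_s) & (dist < p.delta_d_m) & _speed_ok(v[1:], p)
    # segment starts: index 0 plus every fix that failed to join
    breaks = np.flatnonzero(~joins) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])  # exclusive
    out: list[Stop] = []
    for s, e in zip(starts, ends):
        dwell = t[e - 1] - t[s]
        if dwell >= p.min_dwell_s:
            loc = GeoPoint(float(lat[s:e].mean()), float(lon[s:e].mean()))
            out.append(
                Stop(
                    location=loc,
                    start=traj.records[s].t,
                    end=traj.records[e - 1].t,
                    kind=StopKind.FULL_SIGNAL,
                    member_count=int(e - s),
                )
            )
    return out


def detect_no_signal(traj: Trajectory, p: StopParams) -> list[Stop]:
    """Emit a stop for each signal gap bracketed by two nearby fixes.

    A consecutive pair with time gap > gap_t and displacement < max_gap_jump
    becomes a two-member stop at the pair midpoint; larger displacements are
    treated as untracked travel (e.g. underground transit) and skipped. Speed
    is ignored: the bracketing fixes may belong to the trips before and after
    the dwell.
    """
    lat, lon, t, _ = traj.arrays()
    if len(t) < 2:
        return []
    from .geo import haversine_arrays

    dt = np.diff(t)
    dist = haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    idx = np.flatnonzero((dt > p.gap_t_s) & (dist < p.max_gap_jump_m))
    out: list[Stop] = []
    for i in idx:
        loc = GeoPoint(
            float((lat[i] + lat[i + 1]) / 2.0), float((lon[i] + lon[i + 1]) / 2.0)
        )
        out.append(
            Stop(
                location=loc,
                start=traj.records[i].t,
                end=traj.records[i + 1].t,
                kind=StopKind.NO_SIGNAL,
                member_count=2,
            )
        )
    return out


def _merge_pair(a: Stop, b: Stop) -> Stop:
    w = a.member_count + b.member_count
    lat = (a.location.lat * a.member_count + b.location.lat * b.member_count) / w
    lon = (a.location.lon * a.member_count + b.location.lon * b.member_count) / w
    return Stop(
        location=GeoPoint(lat, lon),
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        kind=StopKind.MERGED,
        member_count=w,
    )


def merge_adjacent(stops: list[Stop], p: StopParams) -> list[Stop]:
    """Sweep chronological candidates, merging neighbours that are close in
    both space (< delta_d between centroids) and time (gap < gap_t).

    The merged stop (member-count-weighted centroid) re-enters the sweep, so
    chains of nearby candidates collapse into one stop. Idempotent.
    """
    if not stops:
        return []
    stops = sorted(stops, key=lambda s: (s.start, s.end))
    out = [stops[0]]
    for s in stops[1:]:
        prev = out[-1]
        gap = (s.start - prev.end).total_seconds()
        if gap < p.gap_t_s and haversine(prev.location, s.location) < p.delta_d_m:
            out[-1] = _merge_pair(prev, s)
        else:
            out.append(s)
    return out


def detect_stops(traj: Trajectory, p: StopParams | None = None) -> StopList:
    """Full pipeline: full-signal ∪ no-signal candidates, time-sorted, merged.

    Deterministic for a fixed trajectory and parameter set.
    """
    if p is None:
        p = StopParams()
    candidates = detect_full_signal(traj, p) + detect_no_signal(traj, p)
    candidates.sort(key=lambda s: (s.start, s.end))
    merged = merge_adjacent(candidates, p)
    final = [s for s in merged if s.dwell_s >= p.min_dwell_s]
    return StopList(subject_id=traj.subject_id, stops=final)
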