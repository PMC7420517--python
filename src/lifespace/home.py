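"""Home-location inference from a stop list.

The home is found by density clustering of stop centroids with DBSCAN
(MinPts = 4, following the classic recommendation for 2-D data) where the
neighbourhood radius Eps is chosen automatically at the knee of the sorted
4th-nearest-neighbour distance curve — the point of sharpest gradient change,
which separates the dense home cluster from scattered out-of-home stops. The
cluster with the most member stops is taken as home (ties: larger total
dwell, then earliest first visit) and the home coordinate is the unweighted
centroid of its member stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geo import GeoPoint, centroid, haversine_arrays
from .stops import StopList

__all__ = [
    "HomeParams",
    "HomeEstimate",
    "k_distance_curve",
    "find_knee",
    "dbscan",
    "infer_home",
]

NOISE = -1


@dataclass
class HomeParams:
    """min_pts: DBSCAN MinPts (default 4); k: k-distance plot order (default 4,
    matching MinPts); eps_override: fixed Eps in metres, skipping the knee."""

    min_pts: int = 4
    k: int = 4
    eps_override: float | None = None

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class HomeEstimate:
    location: GeoPoint
    eps_used_m: float
    cluster_stop_count: int
    cluster_total_dwell_s: float


def _distance_matrix(points: list[GeoPoint]) -> np.ndarray:
    lat = np.array([p.lat for p in points])
    lon = np.array([p.lon for p in points])
    return haversine_arrays(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def k_distance_curve(points: list[GeoPoint], k: int) -> np.ndarray:
    """Each point's distance (m) to its k-th nearest neighbour (self excluded),
    sorted ascending."""
    if len(points) < k + 1:
        raise ValueError(
            f"k-distance curve needs at least {k + 1} points, got {len(points)}; "
            "supply eps_override instead"
        )
    d = _distance_matrix(points)
    d_sorted = np.sort(d, axis=1)
    return np.sort(d_sorted[:, k])  # column 0 is the self-distance


def find_knee(curve: np.ndarray) -> float:
    """Geometric knee of a non-decreasing curve.

    Returns the curve value at the index of maximum perpendicular distance to
    the chord joining the first and last points; the first index wins ties.
    A flat curve has no knee — its common value is returned with a warning.
    """
    y = np.asarray(curve, dtype=float)
    if len(y) < 3:
        raise ValueError("knee detection needs a curve of length >= 3")
    if np.any(np.diff(y) < 0):
        raise ValueError("curve must be non-decreasing")
    if y[-1] == y[0]:
        warnings.warn("flat k-distance curve; no density change to locate", stacklevel=2)
        return float(y[0])
    x = np.arange(len(y), dtype=float)
    # chord from (0, y0) to (n-1, y_end); perpendicular point-line distance
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    return float(y[int(np.argmax(dist))])


def dbscan(points: list[GeoPoint], eps_m: float, min_pts: int) -> np.ndarray:
    """DBSCAN with the haversine metric; returns one label per point, -1 = noise.

    A point is core iff at least ``min_pts`` points (itself included) lie
    within ``eps_m``. Clusters are maximal density-connected sets, seeded by
    scanning points in input order and fully expanded before the next seed, so
    a border point reachable from several clusters belongs to the first one
    that claims it.
    """
    if eps_m < 0:
        raise ValueError("eps must be >= 0")
    n = len(points)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    d = _distance_matrix(points)
    neighbors = d <= eps_m
    core = neighbors.sum(axis=1) >= min_pts
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        # breadth-first expansion from seed i
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            if not core[j]:
                continue
            for m in np.flatnonzero(neighbors[j]):
                if labels[m] == NOISE:
                    labels[m] = cluster
                    frontier.append(int(m))
        cluster += 1
    return labels


def infer_home(stops: StopList, p: HomeParams | None = None) -> HomeEstimate:
    """Locate home as the densest stop cluster.

    Raises if there are too few stops to pick Eps automatically, or if every
    stop is DBSCAN noise at the chosen Eps.
    """
    if p is None:
        p = HomeParams()
    pts = stops.centroids()
    if len(pts) < p.min_pts + 1 and p.eps_override is None:
        raise ValueError(
            f"need at least {p.min_pts + 1} stops to infer home automatically; "
            "supply eps_override (or home coordinates downstream)"
        )
    if p.eps_override is not None:
        eps = float(p.eps_override)
    else:
        eps = find_knee(k_distance_curve(pts, p.k))
    labels = dbscan(pts, eps, p.min_pts)
    if np.all(labels == NOISE):
        raise ValueError(
            "no dense cluster found; supply eps_override or home coordinates"
        )
    best = None
    best_key = None
    for c in range(labels.max() + 1):
        members = [stops.stops[i] for i in np.flatnonzero(labels == c)]
        dwell = sum(s.dwell_s for s in members)
        first = min(s.start for s in members)
        # most stops, then most dwell, then earliest first visit
        key = (len(members), dwell, -first.timestamp())
        if best_key is None or key > best_key:
            best_key = key
            best = members
    assert best is not None
    return HomeEstimate(
        location=centroid([s.location for s in best]),
        eps_used_m=eps,
        cluster_stop_count=len(best),
        cluster_total_dwell_s=sum(s.dwell_s for s in best),
    )
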