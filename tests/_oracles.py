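"""Independent brute-force reference implementations used only as test oracles.

Each oracle recomputes a quantity by a different route than the package
(naive loops, exhaustive enumeration) so that agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

from lifespace.geo import EARTH_RADIUS_M, GeoPoint, haversine


def spherical_law_of_cosines(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance by the spherical law of cosines (an independent
    closed form; adequate for points more than a few metres apart)."""
    p1, p2 = math.radians(a.lat), math.radians(b.lat)
    dl = math.radians(b.lon - a.lon)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_M * math.acos(min(1.0, max(-1.0, c)))


def brute_k_distance(points: list[GeoPoint], k: int) -> list[float]:
    """All-pairs scalar-loop k-th nearest neighbour distances, sorted."""
    out = []
    for i, p in enumerate(points):
        d = sorted(haversine(p, q) for j, q in enumerate(points) if j != i)
        out.append(d[k - 1])
    return sorted(out)


def brute_knee(curve) -> float:
    """Exhaustive perpendicular distance-to-chord over every index."""
    y = [float(v) for v in curve]
    n = len(y)
    x0, y0, x1, y1 = 0.0, y[0], float(n - 1), y[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    best_i, best_d = 0, -1.0
    for i in range(n):
        d = abs(dy * (i - x0) - dx * (y[i] - y0)) / norm
        if d > best_d:  # first index wins ties
            best_i, best_d = i, d
    return y[best_i]


def naive_dbscan(points: list[GeoPoint], eps: float, min_pts: int) -> list[int]:
    """Reference DBSCAN via union-find over core points.

    Core points within eps of each other are unioned; clusters are numbered by
    their minimal core index; a border point joins the first cluster (in that
    order) owning a core neighbour. Matches the scan-order claim rule.
    """
    n = len(points)
    d = [[haversine(points[i], points[j]) for j in range(n)] for i in range(n)]
    core = [sum(1 for j in range(n) if d[i][j] <= eps) >= min_pts for i in range(n)]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if not core[i]:
            continue
        for j in range(i + 1, n):
            if core[j] and d[i][j] <= eps:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        if core[i]:
            comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(), key=min)
    labels = [-1] * n
    for c, members in enumerate(ordered):
        for i in members:
            labels[i] = c
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        for c, members in enumerate(ordered):
            if any(d[i][j] <= eps for j in members):
                labels[i] = c
                break
    return labels


def linear_scan_nearby(
    pois, point: GeoPoint, radius_m: float
) -> list[tuple[str, float]]:
    """O(n) scan radius query: (poi id, distance) strictly inside the radius,
    sorted by distance then id."""
    hits = []
    for p in pois:
        dd = haversine(point, p.location)
        if dd < radius_m:
            hits.append((p.id, dd))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def brute_hull_vertices(xy: np.ndarray) -> set[tuple[float, float]]:
    """O(n^3) convex-hull vertex set: endpoints of every directed edge having
    all remaining points strictly to its left."""
    pts = [tuple(map(float, p)) for p in xy]
    n = len(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ax, ay = pts[i]
            bx, by = pts[j]
            if all(
                (bx - ax) * (pts[k][1] - ay) - (by - ay) * (pts[k][0] - ax) > 0
                for k in range(n)
                if k != i and k != j
            ):
                verts.add(pts[i])
                verts.add(pts[j])
    return verts
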