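"""Readers and writers for the package's file formats.

Trajectories come in as CSV (subject_id, timestamp, lat, lon, speed_mps) or
GPX 1.1; stops and annotated stops go out as CSV or GeoJSON FeatureCollections
of Points; POI worlds live in GeoJSON (or CSV with JSON-encoded opening
hours); diaries and Walk Score tables are plain CSV. Naive timestamps are
localised to a configurable timezone (default America/Toronto, the study
region); aware timestamps are taken as-is.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from datetime import datetime
from pathlib import Path
from zoneinfo import ZoneInfo

import pandas as pd

from .activities import (
    POI,
    ActivityCategory,
    AnnotatedStop,
    POIStore,
)
from .evaluation import DiaryEntry, WalkScoreTable
from .geo import GeoPoint, GPSRecord, Trajectory
from .home import HomeEstimate
from .stops import Stop, StopKind, StopList

DEFAULT_TZ = "America/Toronto"

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_trajectory_gpx",
    "write_stops_csv",
    "write_stops_geojson",
    "read_stops_geojson",
    "write_annotated_geojson",
    "read_annotated_geojson",
    "read_pois_geojson",
    "write_pois_geojson",
    "read_pois_csv",
    "read_diary_csv",
    "write_diary_csv",
    "read_walk_scores_csv",
    "write_home_json",
    "read_home_json",
]


def _parse_ts(value: str, tz: str) -> datetime:
    t = pd.Timestamp(value)
    if t.tzinfo is None:
        t = t.tz_localize(ZoneInfo(tz))
    return t.to_pydatetime()


def _check_sorted_unique(records: list[GPSRecord], source: str) -> list[GPSRecord]:
    records = sorted(records, key=lambda r: r.t)
    for a, b in zip(records, records[1:]):
        if a.t == b.t:
            raise ValueError(f"duplicate timestamp {a.t.isoformat()} in {source}")
    return records


def read_trajectory_csv(path: str | Path, tz: str = DEFAULT_TZ) -> Trajectory:
    df = pd.read_csv(path)
    required = {"subject_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("trajectory CSV must contain exactly one subject")
    records = []
    for row in df.itertuples(index=False):
        speed = getattr(row, "speed_mps", None)
        v = None if speed is None or pd.isna(speed) else float(speed)
        records.append(
            GPSRecord(
                lat=float(row.lat),
                lon=float(row.lon),
                t=_parse_ts(str(row.timestamp), tz),
                v=v,
            )
        )
    records = _check_sorted_unique(records, str(path))
    return Trajectory(subject_id=str(subjects[0]), records=records)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "timestamp", "lat", "lon", "speed_mps"])
        for r in traj.records:
            w.writerow(
                [
                    traj.subject_id,
                    r.t.isoformat(),
                    f"{r.lat:.7f}",
                    f"{r.lon:.7f}",
                    "" if r.v is None else f"{r.v:.3f}",
                ]
            )


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def read_trajectory_gpx(
    path: str | Path, subject_id: str | None = None, tz: str = DEFAULT_TZ
) -> Trajectory:
    """Read trkpt lat/lon/time (plus any <speed> extension) from a GPX 1.1 file."""
    root = ET.parse(path).getroot()
    records = []
    for trkpt in root.iter(f"{_GPX_NS}trkpt"):
        time_el = trkpt.find(f"{_GPX_NS}time")
        if time_el is None or time_el.text is None:
            raise ValueError("GPX trkpt without <time> element")
        v = None
        for el in trkpt.iter():
            if el.tag.rsplit("}", 1)[-1] == "speed" and el.text:
                v = float(el.text)
        records.append(
            GPSRecord(
                lat=float(trkpt.attrib["lat"]),
                lon=float(trkpt.attrib["lon"]),
                t=_parse_ts(time_el.text, tz),
                v=v,
            )
        )
    records = _check_sorted_unique(records, str(path))
    return Trajectory(subject_id=subject_id or Path(path).stem, records=records)


def _stop_properties(subject_id: str, i: int, s: Stop) -> dict:
    return {
        "subject_id": subject_id,
        "stop_index": i,
        "lat": s.location.lat,
        "lon": s.location.lon,
        "start": s.start.isoformat(),
        "end": s.end.isoformat(),
        "dwell_s": s.dwell_s,
        "kind": s.kind.value,
        "member_count": s.member_count,
    }


def write_stops_csv(stops: StopList, path: str | Path) -> None:
    rows = [_stop_properties(stops.subject_id, i, s) for i, s in enumerate(stops.stops)]
    pd.DataFrame(
        rows,
        columns=[
            "subject_id", "stop_index", "lat", "lon", "start", "end",
            "dwell_s", "kind", "member_count",
        ],
    ).to_csv(path, index=False)


def _point_feature(lon: float, lat: float, properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [lon, lat]},
        "properties": properties,
    }


def write_stops_geojson(stops: StopList, path: str | Path) -> None:
    features = [
        _point_feature(s.location.lon, s.location.lat, _stop_properties(stops.subject_id, i, s))
        for i, s in enumerate(stops.stops)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def _stop_from_properties(props: dict) -> Stop:
    return Stop(
        location=GeoPoint(float(props["lat"]), float(props["lon"])),
        start=pd.Timestamp(props["start"]).to_pydatetime(),
        end=pd.Timestamp(props["end"]).to_pydatetime(),
        kind=StopKind(props["kind"]),
        member_count=int(props["member_count"]),
    )


def read_stops_geojson(path: str | Path) -> StopList:
    data = json.loads(Path(path).read_text())
    stops, subject = [], "unknown"
    for f in data.get("features", []):
        props = f["properties"]
        subject = props.get("subject_id", subject)
        stops.append(_stop_from_properties(props))
    stops.sort(key=lambda s: s.start)
    return StopList(subject_id=subject, stops=stops)


def write_annotated_geojson(
    annotated: list[AnnotatedStop], subject_id: str, path: str | Path
) -> None:
    features = []
    for i, a in enumerate(annotated):
        props = _stop_properties(subject_id, i, a.stop)
        props.update(
            {
                "label": a.label.value,
                "p_label": a.distribution.probs.get(a.label, 0.0),
                "candidate_count": a.distribution.candidate_count,
                "is_home": a.is_home,
            }
        )
        features.append(_point_feature(a.stop.location.lon, a.stop.location.lat, props))
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_annotated_geojson(path: str | Path) -> tuple[list[AnnotatedStop], str]:
    from .activities import ActivityDistribution

    data = json.loads(Path(path).read_text())
    out, subject = [], "unknown"
    for f in data.get("features", []):
        props = f["properties"]
        subject = props.get("subject_id", subject)
        label = ActivityCategory(props["label"])
        dist = ActivityDistribution(
            probs={label: float(props.get("p_label", 1.0))},
            label=label,
            candidate_count=int(props.get("candidate_count", 0)),
        )
        out.append(
            AnnotatedStop(
                stop=_stop_from_properties(props),
                distribution=dist,
                is_home=bool(props.get("is_home", False)),
            )
        )
    out.sort(key=lambda a: a.stop.start)
    return out, subject


def _hours_to_json(poi: POI) -> dict | None:
    if poi.opening_hours is None:
        return None
    return {d: [list(iv) for iv in ivs] for d, ivs in poi.opening_hours.items()}


def _hours_from_json(obj) -> dict | None:
    if obj is None:
        return None
    return {d: [tuple(iv) for iv in ivs] for d, ivs in obj.items()}


def write_pois_geojson(pois: list[POI], path: str | Path) -> None:
    features = [
        _point_feature(
            p.location.lon,
            p.location.lat,
            {
                "id": p.id,
                "name": p.name,
                "place_type": p.place_type,
                "opening_hours": _hours_to_json(p),
            },
        )
        for p in pois
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_pois_geojson(path: str | Path) -> POIStore:
    data = json.loads(Path(path).read_text())
    pois = []
    for f in data.get("features", []):
        lon, lat = f["geometry"]["coordinates"]
        props = f["properties"]
        pois.append(
            POI(
                id=str(props["id"]),
                name=str(props.get("name", props["id"])),
                place_type=str(props["place_type"]),
                location=GeoPoint(float(lat), float(lon)),
                opening_hours=_hours_from_json(props.get("opening_hours")),
            )
        )
    return POIStore(pois)


def read_pois_csv(path: str | Path) -> POIStore:
    """CSV columns: id, name, place_type, lat, lon, opening_hours (JSON or blank)."""
    df = pd.read_csv(path)
    pois = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "opening_hours", None)
        hours = None
        if raw is not None and not pd.isna(raw) and str(raw).strip():
            hours = _hours_from_json(json.loads(str(raw)))
        pois.append(
            POI(
                id=str(row.id),
                name=str(row.name),
                place_type=str(row.place_type),
                location=GeoPoint(float(row.lat), float(row.lon)),
                opening_hours=hours,
            )
        )
    return POIStore(pois)


def read_diary_csv(path: str | Path, tz: str = DEFAULT_TZ) -> list[DiaryEntry]:
    df = pd.read_csv(path)
    entries = [
        DiaryEntry(
            arrival=_parse_ts(str(row.arrival), tz),
            departure=_parse_ts(str(row.departure), tz),
            location=GeoPoint(float(row.lat), float(row.lon)),
            category=ActivityCategory(str(row.category)),
        )
        for row in df.itertuples(index=False)
    ]
    entries.sort(key=lambda e: e.arrival)
    return entries


def write_diary_csv(
    entries: list[DiaryEntry], subject_id: str, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "arrival", "departure", "lat", "lon", "category"])
        for e in entries:
            w.writerow(
                [
                    subject_id,
                    e.arrival.isoformat(),
                    e.departure.isoformat(),
                    f"{e.location.lat:.7f}",
                    f"{e.location.lon:.7f}",
                    e.category.value,
                ]
            )


def read_walk_scores_csv(path: str | Path) -> WalkScoreTable:
    df = pd.read_csv(path)
    return WalkScoreTable(
        [
            (GeoPoint(float(r.lat), float(r.lon)), int(r.score))
            for r in df.itertuples(index=False)
        ]
    )


def write_home_json(home: HomeEstimate, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "lat": home.location.lat,
                "lon": home.location.lon,
                "eps_m": home.eps_used_m,
                "cluster_stop_count": home.cluster_stop_count,
                "cluster_total_dwell_s": home.cluster_total_dwell_s,
            },
            indent=1,
        )
    )


def read_home_json(path: str | Path) -> HomeEstimate:
    data = json.loads(Path(path).read_text())
    return HomeEstimate(
        location=GeoPoint(float(data["lat"]), float(data["lon"])),
        eps_used_m=float(data["eps_m"]),
        cluster_stop_count=int(data["cluster_stop_count"]),
        cluster_total_dwell_s=float(data["cluster_total_dwell_s"]),
    )
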