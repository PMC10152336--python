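"""Green-space database and proximity detection.

The engine never stores user coordinates. A position fix is compared against
a database of preselected green spaces (parks, forests, walking trails) and
only the *outcome* — a timestamp, the space id, and its type — is recorded
(:class:`GeoObservation`). Distances are great-circle (haversine) on a
sphere of mean Earth radius; at the 300-m geofence scale the difference from
an ellipsoidal geodesic is far below a meter.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import csv
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pydantic import BaseModel, Field

#: Mean Earth radius in meters (IUGG R1).
EARTH_RADIUS_M = 6_371_008.8

#: Default geofence radius in meters.
DEFAULT_RADIUS_M = 300.0


class GeofenceError(ValueError):
    """Malformed green-space data or invalid coordinates."""


class GreenSpaceType(str, Enum):
    PARK = "park"
    FOREST = "forest"
    WALKING_TRAIL = "walking_trail"

    @property
    def display(self) -> str:
        """Human-readable form substituted into message text."""
        return self.value.replace("_", " ")


class Position(NamedTuple):
    """A WGS84 position fix in decimal degrees."""

    lat: float
    lon: float


class GreenSpace(BaseModel):
    model_config = {"frozen": True}

    space_id: str = Field(min_length=1)
    name: str
    type: GreenSpaceType
    lat: float = Field(ge=-90.0, le=90.0)
    lon: float = Field(ge=-180.0, le=180.0)


@dataclass(frozen=True)
class GeoObservation:
    """Privacy-preserving record of one geofence hit: no user coordinates."""

    timestamp: dt.datetime
    green_space_type: GreenSpaceType
    space_id: str


def _check_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise GeofenceError(f"coordinates out of range: ({lat}, {lon})")


def haversine_m(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance in meters between two (lat, lon) points."""
    lat1, lon1 = float(a[0]), float(a[1])
    lat2, lon2 = float(b[0]), float(b[1])
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    s = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(s)))


def destination_point(
    lat: float, lon: float, bearing_deg: float, distance_m: float
) -> Position:
    """Point reached from (lat, lon) after ``distance_m`` along a bearing.

    Standard spherical direct formula on the same sphere as
    :func:`haversine_m`, so constructed and measured distances agree.
    """
    _check_coords(lat, lon)
    delta = distance_m / EARTH_RADIUS_M
    theta = math.radians(bearing_deg)
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = math.degrees(lam2)
    if lon2 > 180.0:
        lon2 -= 360.0
    elif lon2 < -180.0:
        lon2 += 360.0
    return Position(math.degrees(phi2), lon2)


class GreenSpaceDB:
    """Ordered collection of green spaces with vectorized distance queries."""

    def __init__(self, spaces: Iterable[GreenSpace]) -> None:
        self.spaces: list[GreenSpace] = list(spaces)
        ids = [s.space_id for s in self.spaces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GeofenceError(f"duplicate space_id values: {dupes}")
        self._phi = np.radians(np.array([s.lat for s in self.spaces], dtype=float))
        self._lam = np.radians(np.array([s.lon for s in self.spaces], dtype=float))

    def __len__(self) -> int:
        return len(self.spaces)

    def __iter__(self):
        return iter(self.spaces)

    def __eq__(self, other) -> bool:
        return isinstance(other, GreenSpaceDB) and self.spaces == other.spaces

    def distances_m(self, pos: Sequence[float]) -> np.ndarray:
        """Haversine distance from ``pos`` to every space, in db order."""
        lat, lon = float(pos[0]), float(pos[1])
        _check_coords(lat, lon)
        phi = math.radians(lat)
        lam = math.radians(lon)
        s = (
            np.sin((self._phi - phi) / 2.0) ** 2
            + math.cos(phi) * np.cos(self._phi) * np.sin((self._lam - lam) / 2.0) ** 2
        )
        return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(s)))


@dataclass(frozen=True)
class ProximityHit:
    space: GreenSpace
    distance_m: float


def check_proximity(
    pos: Sequence[float], db: GreenSpaceDB, radius_m: float = DEFAULT_RADIUS_M
) -> ProximityHit | None:
    """Nearest green space within ``radius_m`` of ``pos`` (boundary inclusive).

    Among spaces at equal minimal distance the lexicographically smallest
    ``space_id`` wins, for determinism. Returns ``None`` when the database is
    empty or no space is within range.
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    if len(db) == 0:
        return None
    dists = db.distances_m(pos)
    within = np.flatnonzero(dists <= radius_m)
    if within.size == 0:
        return None
    dmin = dists[within].min()
    candidates = [int(i) for i in within if dists[i] == dmin]
    best = min(candidates, key=lambda i: db.spaces[i].space_id)
    return ProximityHit(space=db.spaces[best], distance_m=float(dmin))


# ---------------------------------------------------------------------------
# File interfaces: CSV and GeoJSON are accepted equivalently.
# ---------------------------------------------------------------------------

_CSV_HEADER = ("space_id", "name", "type", "lat", "lon")


def _space_from_fields(space_id, name, type_, lat, lon, where: str) -> GreenSpace:
    try:
        type_enum = GreenSpaceType(type_)
    except ValueError as exc:
        raise GeofenceError(
            f"{where}: unknown green-space type {type_!r} "
            f"(expected one of {[t.value for t in GreenSpaceType]})"
        ) from exc
    try:
        lat_f, lon_f = float(lat), float(lon)
    except (TypeError, ValueError) as exc:
        raise GeofenceError(f"{where}: malformed coordinates ({lat!r}, {lon!r})") from exc
    if not (-90.0 <= lat_f <= 90.0) or not (-180.0 <= lon_f <= 180.0):
        raise GeofenceError(f"{where}: coordinates out of range ({lat_f}, {lon_f})")
    return GreenSpace(space_id=str(space_id), name=str(name), type=type_enum, lat=lat_f, lon=lon_f)


def load_green_spaces(path) -> GreenSpaceDB:
    """Load a green-space database from CSV or a GeoJSON FeatureCollection."""
    with open(path, encoding="utf-8") as fh:
        head = fh.read(64)
    if head.lstrip().startswith("{"):
        return _load_geojson(path)
    return _load_csv(path)


def _load_csv(path) -> GreenSpaceDB:
    spaces = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _CSV_HEADER if c not in fields]
        if missing:
            raise GeofenceError(f"green-space file missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            spaces.append(
                _space_from_fields(
                    row["space_id"], row["name"], row["type"], row["lat"], row["lon"],
                    where=f"row {i}",
                )
            )
    return GreenSpaceDB(spaces)


def _load_geojson(path) -> GreenSpaceDB:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeofenceError("GeoJSON root must be a FeatureCollection")
    spaces = []
    for i, feat in enumerate(doc.get("features", [])):
        where = f"feature {i}"
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise GeofenceError(f"{where}: geometry must be a Point")
        coords = geom.get("coordinates") or []
        if len(coords) < 2:
            raise GeofenceError(f"{where}: malformed coordinates {coords!r}")
        lon, lat = coords[0], coords[1]  # GeoJSON order is (lon, lat)
        props = feat.get("properties") or {}
        for key in ("space_id", "name", "type"):
            if key not in props:
                raise GeofenceError(f"{where}: missing property {key!r}")
        spaces.append(
            _space_from_fields(props["space_id"], props["name"], props["type"], lat, lon, where)
        )
    return GreenSpaceDB(spaces)


def write_green_spaces(db: GreenSpaceDB, path, fmt: str = "csv") -> None:
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for s in db:
                writer.writerow([s.space_id, s.name, s.type.value, repr(s.lat), repr(s.lon)])
    elif fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
                    "properties": {"space_id": s.space_id, "name": s.name, "type": s.type.value},
                }
                for s in db
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'geojson')")
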