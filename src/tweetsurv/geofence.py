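"""Radial geofencing of tweets around points of interest.

Each message is assigned to the *airport* collection when it lies within
``airport_radius_km`` (default 3 km) of a large airport, to the *hospital*
collection within ``hospital_radius_km`` (default 0.2 km) of a hospital,
and to the background *geolocated* collection when in neither.  The two
memberships are independent flags — a tweet can sit inside both fences.

Distances are great-circle on a sphere of radius 6371 km; at the 0.2–3 km
scales of the fences the ellipsoidal correction is sub-metre and ignored.
Boundary is inclusive (distance <= radius), which keeps membership monotone
in the radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Tweet
from .errors import POIFormatError, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

KIND_AIRPORT = "airport"
KIND_HOSPITAL = "hospital"


@dataclass(frozen=True)
class POI:
    """A point of interest (airport or hospital) with spherical coordinates."""

    poi_id: str
    kind: str  # "airport" | "hospital"
    name: str
    lat: float
    lon: float
    poi_class: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (KIND_AIRPORT, KIND_HOSPITAL):
            raise ValidationError(f"unknown POI kind {self.kind!r}")
        _check_coords(self.lat, self.lon)


@dataclass(frozen=True)
class Radii:
    """Fence radii in kilometres."""

    airport_km: float = 3.0
    hospital_km: float = 0.2


@dataclass(frozen=True)
class CollectionMembership:
    """Per-tweet fence membership with nearest-POI distances (km)."""

    tweet_id: str
    in_airport: bool
    in_hospital: bool
    nearest_airport_km: float
    nearest_hospital_km: float

    @property
    def collection_label(self) -> str:
        """Exclusive label for reporting: airport / hospital / both / geolocated."""
        if self.in_airport and self.in_hospital:
            return "both"
        if self.in_airport:
            return KIND_AIRPORT
        if self.in_hospital:
            return KIND_HOSPITAL
        return "geolocated"


def _check_coords(lat: float, lon: float) -> None:
    if not -90.0 <= lat <= 90.0:
        raise ValidationError(f"latitude out of bounds: {lat}")
    if not -180.0 <= lon <= 180.0:
        raise ValidationError(f"longitude out of bounds: {lon}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two lat/lon points (degrees)."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _haversine_matrix_km(
    lats: np.ndarray, lons: np.ndarray, poi_lats: np.ndarray, poi_lons: np.ndarray
) -> np.ndarray:
    """Vectorized pairwise distances, shape (n_points, n_pois)."""
    p = np.radians(lats)[:, None]
    q = np.radians(poi_lats)[None, :]
    dphi = q - p
    dlam = np.radians(poi_lons)[None, :] - np.radians(lons)[:, None]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p) * np.cos(q) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def load_pois(
    path: str | Path, kind: str, class_filter: str | None = None
) -> list[POI]:
    """Read a POI CSV (OurAirports-compatible columns).

    Required columns: ``id, type, name, latitude_deg, longitude_deg``.
    ``class_filter`` keeps only rows whose ``type`` equals it (e.g.
    ``"large_airport"``); rows with blank/invalid coordinates are skipped
    and logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "type", "name", "latitude_deg", "longitude_deg"}
    missing = required - set(df.columns)
    if missing:
        raise POIFormatError(f"POI file missing columns: {sorted(missing)}")
    pois: list[POI] = []
    for row in df.itertuples(index=False):
        if class_filter is not None and row.type != class_filter:
            continue
        try:
            lat = float(row.latitude_deg)
            lon = float(row.longitude_deg)
            _check_coords(lat, lon)
        except (ValueError, ValidationError):
            logger.warning("skipping POI %r: invalid coordinates", row.id)
            continue
        pois.append(POI(str(row.id), kind, row.name, lat, lon, poi_class=row.type))
    return pois


def classify(
    tweet: Tweet,
    airports: Sequence[POI],
    hospitals: Sequence[POI],
    radii: Radii = Radii(),
) -> CollectionMembership:
    """Fence membership of a single tweet (brute-force nearest POI)."""
    nearest_a = min(
        (haversine_km(tweet.lat, tweet.lon, p.lat, p.lon) for p in airports),
        default=math.inf,
    )
    nearest_h = min(
        (haversine_km(tweet.lat, tweet.lon, p.lat, p.lon) for p in hospitals),
        default=math.inf,
    )
    return CollectionMembership(
        tweet_id=tweet.tweet_id,
        in_airport=nearest_a <= radii.airport_km,
        in_hospital=nearest_h <= radii.hospital_km,
        nearest_airport_km=nearest_a,
        nearest_hospital_km=nearest_h,
    )


def classify_corpus(
    tweets: Sequence[Tweet],
    airports: Sequence[POI],
    hospitals: Sequence[POI],
    radii: Radii = Radii(),
) -> list[CollectionMembership]:
    """Vectorized membership for a whole corpus; identical to :func:`classify`."""
    if not tweets:
        return []
    lats = np.array([t.lat for t in tweets])
    lons = np.array([t.lon for t in tweets])
    nearest = {}
    for label, pois in ((KIND_AIRPORT, airports), (KIND_HOSPITAL, hospitals)):
        if pois:
            d = _haversine_matrix_km(
                lats,
                lons,
                np.array([p.lat for p in pois]),
                np.array([p.lon for p in pois]),
            )
            nearest[label] = d.min(axis=1)
        else:
            nearest[label] = np.full(len(tweets), np.inf)
    return [
        CollectionMembership(
            tweet_id=t.tweet_id,
            in_airport=bool(nearest[KIND_AIRPORT][i] <= radii.airport_km),
            in_hospital=bool(nearest[KIND_HOSPITAL][i] <= radii.hospital_km),
            nearest_airport_km=float(nearest[KIND_AIRPORT][i]),
            nearest_hospital_km=float(nearest[KIND_HOSPITAL][i]),
        )
        for i, t in enumerate(tweets)
    ]


class GridIndex:
    """Optional latitude-band index for nearest-POI queries.

    Returns distances identical to the brute-force path.  POIs are bucketed
    into latitude bands of ``cell_deg`` degrees; a query scans bands
    outward from its own and stops once every unexplored band is provably
    farther than the current best — the latitude separation alone already
    bounds the great-circle distance from below (one degree of latitude is
    pi*R/180 km everywhere on the sphere), so the early stop is exact at
    any latitude and needs no longitude bookkeeping.
    """

    KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0

    def __init__(self, pois: Sequence[POI], cell_deg: float = 1.0):
        self.pois = list(pois)
        self.cell_deg = float(cell_deg)
        self._bands: dict[int, list[POI]] = {}
        for p in self.pois:
            self._bands.setdefault(self._band(p.lat), []).append(p)

    def _band(self, lat: float) -> int:
        return int(math.floor(lat / self.cell_deg))

    def nearest_km(self, lat: float, lon: float) -> float:
        if not self.pois:
            return math.inf
        _check_coords(lat, lon)
        bi = self._band(lat)
        best = math.inf
        max_ring = int(180.0 / self.cell_deg) + 2
        for ring in range(max_ring):
            # any point >= ring-1 bands away differs in latitude by at least
            # (ring-1)*cell_deg degrees, hence by that many lat-km
            if ring > 0 and (ring - 1) * self.cell_deg * self.KM_PER_DEG_LAT > best:
                break
            bands = {bi + ring, bi - ring} if ring else {bi}
            for b in bands:
                for p in self._bands.get(b, ()):
                    d = haversine_km(lat, lon, p.lat, p.lon)
                    if d < best:
                        best = d
        return best
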