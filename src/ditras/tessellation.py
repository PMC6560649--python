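"""Weighted spatial tessellations and the gravity origin–destination matrix.

A weighted spatial tessellation is the discrete mobility space of a
simulation: a set of locations, each identified by the coordinates of its
centroid and carrying a positive *relevance* weight measuring its popularity
(e.g. calls served by a phone tower, stops in a census cell, or population
density).  The tessellation is the source of two sampling primitives used
throughout the package:

* relevance-proportional sampling, used to place agents' home locations;
* the gravity origin–destination matrix ``p_ij ∝ r_i r_j / d_ij²``, used by
  the density-EPR exploration mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "Location",
    "WeightedSpatialTessellation",
    "ODMatrix",
    "distance",
    "haversine_matrix",
    "build_od_matrix",
    "sample_by_relevance",
    "read_tessellation_csv",
    "write_tessellation_csv",
    "read_tessellation_geojson",
    "write_tessellation_geojson",
]


@dataclass(frozen=True)
class Location:
    """A tessellation cell: centroid coordinates plus a relevance weight."""

    id: str
    lat: float
    lon: float
    relevance: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of [-90, 90] for location {self.id!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of [-180, 180] for location {self.id!r}")
        if not self.relevance > 0:
            raise ValueError(f"relevance must be positive, got {self.relevance} for location {self.id!r}")


class WeightedSpatialTessellation:
    """Ordered collection of :class:`Location` with unique ids and coordinates.

    The order of the locations fixes the index space of every derived matrix
    and vector (gravity matrix rows/columns, relevance vector).
    """

    def __init__(self, locations: Iterable[Location]):
        self.locations: list[Location] = list(locations)
        if len(self.locations) < 2:
            raise ValueError("a tessellation needs at least 2 locations")
        ids = [loc.id for loc in self.locations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate location ids: {dup}")
        coords = {}
        for loc in self.locations:
            key = (loc.lat, loc.lon)
            if key in coords:
                raise ValueError(
                    f"locations {coords[key]!r} and {loc.id!r} share coordinates {key}; "
                    "coincident centroids give an unbounded gravity weight"
                )
            coords[key] = loc.id
        self._index = {loc.id: i for i, loc in enumerate(self.locations)}
        self.lats = np.array([loc.lat for loc in self.locations])
        self.lons = np.array([loc.lon for loc in self.locations])
        self.relevances = np.array([loc.relevance for loc in self.locations], dtype=float)

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self) -> Iterator[Location]:
        return iter(self.locations)

    def __getitem__(self, i: int) -> Location:
        return self.locations[i]

    def index_of(self, location_id: str) -> int:
        return self._index[location_id]

    def by_id(self, location_id: str) -> Location:
        return self.locations[self._index[location_id]]

    @property
    def ids(self) -> list[str]:
        return [loc.id for loc in self.locations]

    def distance_matrix(self) -> np.ndarray:
        """Pairwise great-circle distances in kilometres (symmetric, zero diagonal).

        Computed once and cached; locations are immutable.
        """
        if not hasattr(self, "_dmat"):
            self._dmat = haversine_matrix(self.lats, self.lons)
        return self._dmat


def distance(a: Location, b: Location) -> float:
    """Great-circle (haversine) distance between two locations in kilometres."""
    return float(
        _haversine(
            np.radians(a.lat), np.radians(a.lon), np.radians(b.lat), np.radians(b.lon)
        )
    )


def _haversine(lat1, lon1, lat2, lon2):
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_matrix(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    la = np.radians(np.asarray(lats, dtype=float))
    lo = np.radians(np.asarray(lons, dtype=float))
    return _haversine(la[:, None], lo[:, None], la[None, :], lo[None, :])


class ODMatrix:
    """Gravity trip-probability matrix over a tessellation.

    ``probs`` is an m×m array with zero diagonal whose entries sum to 1
    jointly; ``probs[i, j]`` is the probability that a trip in the population
    goes from location i to location j.
    """

    def __init__(self, probs: np.ndarray, ids: Sequence[str]):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError("OD matrix must be square")
        if probs.shape[0] != len(ids):
            raise ValueError("id list does not match matrix size")
        if np.any(probs < 0) or np.any(np.diag(probs) != 0):
            raise ValueError("OD matrix needs non-negative entries and a zero diagonal")
        if not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("OD matrix entries must sum to 1")
        self.probs = probs
        self.ids = list(ids)

    def row(self, i: int) -> np.ndarray:
        """Unnormalised conditional weights for trips out of location ``i``."""
        return self.probs[i]


def build_od_matrix(
    tess: WeightedSpatialTessellation, exponent: float = 2.0
) -> ODMatrix:
    """Gravity OD matrix ``p_ij = (1/Z) r_i r_j / d_ij^exponent``.

    Z normalises the whole matrix jointly (sum over all ordered pairs i≠j).
    Coincident locations are rejected at tessellation construction, so all
    off-diagonal distances are positive.
    """
    d = tess.distance_matrix()
    off = ~np.eye(len(tess), dtype=bool)
    if np.any(d[off] == 0):  # defensive: tessellation construction already forbids this
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"zero distance between {tess.ids[i]!r} and {tess.ids[j]!r}")
    r = tess.relevances
    with np.errstate(divide="ignore"):
        w = np.where(off, r[:, None] * r[None, :] / np.where(off, d, 1.0) ** exponent, 0.0)
    return ODMatrix(w / w.sum(), tess.ids)


def sample_by_relevance(tess: WeightedSpatialTessellation, rng: np.random.Generator) -> Location:
    """Draw a location with probability proportional to its relevance."""
    p = tess.relevances / tess.relevances.sum()
    return tess.locations[int(rng.choice(len(tess), p=p))]


# ---------------------------------------------------------------------------
# IO: CSV with header location_id,lat,lon,relevance; GeoJSON FeatureCollection
# of Point features (the centroid) with a "relevance" property.

def read_tessellation_csv(path) -> WeightedSpatialTessellation:
    df = pd.read_csv(path, dtype={"location_id": str}, float_precision="round_trip")
    required = {"location_id", "lat", "lon", "relevance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tessellation CSV missing columns: {sorted(missing)}")
    return WeightedSpatialTessellation(
        Location(row.location_id, float(row.lat), float(row.lon), float(row.relevance))
        for row in df.itertuples(index=False)
    )


def write_tessellation_csv(tess: WeightedSpatialTessellation, path) -> None:
    pd.DataFrame(
        {
            "location_id": tess.ids,
            "lat": tess.lats,
            "lon": tess.lons,
            "relevance": tess.relevances,
        }
    ).to_csv(path, index=False)


def read_tessellation_geojson(path) -> WeightedSpatialTessellation:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    locations = []
    for feat in fc["features"]:
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise ValueError("tessellation features must be Point centroids")
        lon, lat = geom["coordinates"]
        props = feat.get("properties", {})
        locations.append(
            Location(
                str(props.get("location_id", feat.get("id"))),
                float(lat),
                float(lon),
                float(props["relevance"]),
            )
        )
    return WeightedSpatialTessellation(locations)


def write_tessellation_geojson(tess: WeightedSpatialTessellation, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [loc.lon, loc.lat]},
                "properties": {"location_id": loc.id, "relevance": loc.relevance},
            }
            for loc in tess
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)
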