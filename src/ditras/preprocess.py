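"""Readers, writers and cleaning rules for CDR-like and GPS location records.

CDR (call detail record) streams sample a user's location only when she is
active, so users with too few records or a single location carry no usable
mobility signal.  The cleaning pipeline, applied per user in this order:

1. drop locations holding a fraction ``n_i/N ≤ 0.005`` of the user's records;
2. drop users left with a single location;
3. drop users whose record rate over the observation span is below
   0.5 records per hour.

GPS streams are continuous while a vehicle moves; gaps longer than a stop
threshold (default 20 minutes) split the stream into trips, and each trip
contributes its origin and destination stop, mapped to a tessellation cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tessellation import WeightedSpatialTessellation, haversine_matrix

__all__ = [
    "RawRecord",
    "GpsPing",
    "filter_cdr_users",
    "segment_gps_trips",
    "nearest_cell_mapper",
    "read_cdr_csv",
    "write_cdr_csv",
    "read_gps_csv",
    "write_gps_csv",
]

LOCATION_FRACTION_THRESHOLD = 0.005
MIN_RECORDS_PER_HOUR = 0.5
DEFAULT_STOP_THRESHOLD_S = 20 * 60


@dataclass(frozen=True)
class RawRecord:
    """One location observation: epoch seconds, user and cell/tower id."""

    timestamp: float
    user_id: str
    location_id: str


@dataclass(frozen=True)
class GpsPing:
    timestamp: float
    vehicle_id: str
    lat: float
    lon: float


def filter_cdr_users(
    records_by_user: Mapping[str, Sequence[RawRecord]],
    location_fraction: float = LOCATION_FRACTION_THRESHOLD,
    min_rate_per_hour: float = MIN_RECORDS_PER_HOUR,
) -> dict[str, list[RawRecord]]:
    """Apply the three CDR cleaning rules; returns retained users' records.

    The observation span used for the rate filter is the last minus first
    timestamp of the whole (input) dataset.  The filter is idempotent:
    dropping rare locations only raises the remaining location fractions,
    and re-running on the cleaned output changes nothing.
    """
    if not records_by_user:
        raise ValueError("no records")
    all_times = [r.timestamp for recs in records_by_user.values() for r in recs]
    span_hours = (max(all_times) - min(all_times)) / 3600.0

    out: dict[str, list[RawRecord]] = {}
    for user, recs in records_by_user.items():
        recs = sorted(recs, key=lambda r: r.timestamp)
        n_total = len(recs)
        counts: dict[str, int] = {}
        for r in recs:
            counts[r.location_id] = counts.get(r.location_id, 0) + 1
        keep_locs = {loc for loc, c in counts.items() if c / n_total > location_fraction}
        cleaned = [r for r in recs if r.location_id in keep_locs]
        if len(keep_locs) < 2:
            continue
        if span_hours > 0 and len(cleaned) / span_hours < min_rate_per_hour:
            continue
        out[user] = cleaned
    return out


def nearest_cell_mapper(tess: WeightedSpatialTessellation) -> Callable[[float, float], str]:
    """Map a (lat, lon) point to the id of the nearest tessellation centroid."""

    def mapper(lat: float, lon: float) -> str:
        d = haversine_matrix(
            np.append(tess.lats, lat), np.append(tess.lons, lon)
        )[-1, :-1]
        return tess.ids[int(np.argmin(d))]

    return mapper


def segment_gps_trips(
    pings: Sequence[GpsPing],
    cell_mapper: Callable[[float, float], str | None],
    stop_threshold_s: float = DEFAULT_STOP_THRESHOLD_S,
) -> tuple[list[RawRecord], int]:
    """Split one vehicle's ping stream into trips at long gaps.

    A gap longer than ``stop_threshold_s`` between consecutive pings ends a
    trip; each trip contributes its origin and destination stop as
    CDR-like records.  Pings the ``cell_mapper`` cannot place (returns
    ``None``) are dropped; the count of dropped pings is returned alongside.
    """
    pings = sorted(pings, key=lambda p: p.timestamp)
    mapped: list[RawRecord] = []
    dropped = 0
    for p in pings:
        cell = cell_mapper(p.lat, p.lon)
        if cell is None:
            dropped += 1
        else:
            mapped.append(RawRecord(p.timestamp, p.vehicle_id, cell))
    if not mapped:
        return [], dropped

    stops: list[RawRecord] = []
    trip_start = mapped[0]
    prev = mapped[0]
    for rec in mapped[1:]:
        if rec.timestamp - prev.timestamp > stop_threshold_s:
            stops.extend([trip_start, prev])
            trip_start = rec
        prev = rec
    stops.extend([trip_start, prev])
    return stops, dropped


# ---------------------------------------------------------------------------
# CSV dialects: CDR `timestamp,user_id,location_id`; GPS `timestamp,vehicle_id,lat,lon`.
# Timestamps may be epoch seconds or ISO-8601.

def _parse_times(col: pd.Series) -> np.ndarray:
    try:
        return col.astype(float).to_numpy()
    except (ValueError, TypeError):
        return pd.to_datetime(col).astype("int64").to_numpy() / 1e9


def read_cdr_csv(path) -> dict[str, list[RawRecord]]:
    df = pd.read_csv(path, dtype={"user_id": str, "location_id": str}, float_precision="round_trip")
    times = _parse_times(df["timestamp"])
    by_user: dict[str, list[RawRecord]] = {}
    for ts, user, loc in zip(times, df["user_id"], df["location_id"]):
        by_user.setdefault(user, []).append(RawRecord(float(ts), user, loc))
    for user in by_user:
        by_user[user].sort(key=lambda r: r.timestamp)
    return by_user


def write_cdr_csv(records: Iterable[RawRecord], path) -> None:
    df = pd.DataFrame(
        [(r.timestamp, r.user_id, r.location_id) for r in records],
        columns=["timestamp", "user_id", "location_id"],
    )
    df.to_csv(path, index=False)


def read_gps_csv(path) -> dict[str, list[GpsPing]]:
    df = pd.read_csv(path, dtype={"vehicle_id": str}, float_precision="round_trip")
    times = _parse_times(df["timestamp"])
    by_vehicle: dict[str, list[GpsPing]] = {}
    for ts, veh, lat, lon in zip(times, df["vehicle_id"], df["lat"], df["lon"]):
        by_vehicle.setdefault(veh, []).append(GpsPing(float(ts), veh, float(lat), float(lon)))
    for veh in by_vehicle:
        by_vehicle[veh].sort(key=lambda p: p.timestamp)
    return by_vehicle


def write_gps_csv(pings: Iterable[GpsPing], path) -> None:
    df = pd.DataFrame(
        [(p.timestamp, p.vehicle_id, p.lat, p.lon) for p in pings],
        columns=["timestamp", "vehicle_id", "lat", "lon"],
    )
    df.to_csv(path, index=False)
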