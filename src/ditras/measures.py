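"""The nine standard mobility measures and RMSE / KL distribution comparison.

Given a cohort of sampled trajectories the suite computes the empirical
distributions of: trip distance Δr, radius of gyration r_g, mobility entropy
S^unc, location frequency by rank f(L), visits per location V, distinct
locations per user N_u, trips per hour of day T, trips per day D, and stay
time Δt.  A *visit* is one maximal stay (an arrival event).  Two suites with
identical binning are compared measure-by-measure with the root mean square
error and the Kullback–Leibler divergence (natural log, additive
ε-smoothing).

Binning conventions (package conventions, fixed so any two cohorts are
comparable): geometric bins with ratio 1.5 for Δr, r_g, V and Δt; unit
integer bins for N_u and D; 24 hour-of-day bins for T; 20 linear bins on
[0, 1] for S^unc; f(L) truncated at rank 20.  Values beyond the last edge
are clipped into the final bin so every distribution stays normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SampledMobilityTrajectory
from .tessellation import WeightedSpatialTessellation, haversine_matrix, _haversine

__all__ = [
    "StayRecord",
    "EmpiricalDistribution",
    "MeasureSuite",
    "MEASURE_NAMES",
    "extract_stays_and_trips",
    "radius_of_gyration",
    "mobility_entropy",
    "population_measures",
    "rmse",
    "kl_divergence",
    "compare_suites",
    "plot_suite",
]

MEASURE_NAMES = (
    "trip_distance",
    "radius_of_gyration",
    "entropy",
    "location_frequency",
    "visits_per_location",
    "locations_per_user",
    "trips_per_hour",
    "trips_per_day",
    "stay_time",
)

KL_EPS = 1e-12
RANK_CUTOFF = 20


@dataclass(frozen=True)
class StayRecord:
    """A maximal constant-location run of one agent."""

    agent_id: int
    location_id: str
    start_slot: int
    length_slots: int


@dataclass(frozen=True)
class EmpiricalDistribution:
    """A normalized histogram: strictly increasing edges, probabilities sum 1."""

    bin_edges: tuple[float, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self):
        edges = np.asarray(self.bin_edges)
        probs = np.asarray(self.probabilities)
        if len(edges) != len(probs) + 1:
            raise ValueError("need len(edges) == len(probabilities) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @classmethod
    def from_values(cls, values, edges) -> "EmpiricalDistribution":
        values = np.asarray(values, dtype=float)
        edges = np.asarray(edges, dtype=float)
        if values.size == 0:
            raise ValueError("cannot build a distribution from no values")
        # clip into the covered range so mass is conserved
        clipped = np.clip(values, edges[0], np.nextafter(edges[-1], -np.inf))
        counts, _ = np.histogram(clipped, bins=edges)
        return cls(tuple(edges), tuple(counts / counts.sum()))


def _geometric_edges(anchor: float, ratio: float, n_bins: int, zero_floor: bool) -> np.ndarray:
    edges = anchor * ratio ** np.arange(n_bins)
    return np.concatenate([[0.0], edges]) if zero_floor else edges


# Fixed binning per measure (see module docstring).
_EDGES = {
    "trip_distance": _geometric_edges(0.1, 1.5, 35, zero_floor=True),
    "radius_of_gyration": _geometric_edges(0.1, 1.5, 35, zero_floor=True),
    "entropy": np.linspace(0.0, 1.0, 21),
    "location_frequency": np.arange(RANK_CUTOFF + 1) + 0.5,
    "visits_per_location": _geometric_edges(0.5, 1.5, 31, zero_floor=False),
    "locations_per_user": np.arange(0, 1001) + 0.5,
    "trips_per_hour": np.arange(25, dtype=float),
    "trips_per_day": np.arange(-0.5, 49.5),
    "stay_time": _geometric_edges(0.5, 1.5, 29, zero_floor=True),
}


@dataclass(frozen=True)
class MeasureSuite:
    """The nine named empirical distributions of a cohort."""

    distributions: dict[str, EmpiricalDistribution]

    def __post_init__(self):
        missing = set(MEASURE_NAMES) - set(self.distributions)
        if missing:
            raise ValueError(f"missing measures: {sorted(missing)}")

    def __getitem__(self, name: str) -> EmpiricalDistribution:
        return self.distributions[name]

    def to_json(self, path) -> None:
        payload = {
            name: {"bin_edges": list(d.bin_edges), "probabilities": list(d.probabilities)}
            for name, d in self.distributions.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MeasureSuite":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {
                name: EmpiricalDistribution(tuple(d["bin_edges"]), tuple(d["probabilities"]))
                for name, d in payload.items()
            }
        )


def extract_stays_and_trips(
    traj: SampledMobilityTrajectory,
) -> tuple[list[StayRecord], list[tuple[str, str, int]]]:
    """Maximal constant-location runs and the trips between them.

    A trip joins each pair of consecutive stays and is stamped with the
    arrival slot (the first slot of the destination stay); there are always
    ``len(stays) − 1`` trips.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    stays: list[StayRecord] = []
    for lat, lon, slot, loc_id in traj.entries:
        if stays and stays[-1].location_id == loc_id:
            last = stays[-1]
            stays[-1] = StayRecord(last.agent_id, last.location_id, last.start_slot, last.length_slots + 1)
        else:
            stays.append(StayRecord(traj.agent_id, loc_id, slot, 1))
    trips = [
        (stays[i].location_id, stays[i + 1].location_id, stays[i + 1].start_slot)
        for i in range(len(stays) - 1)
    ]
    return stays, trips


def _visit_counts(stays: Sequence[StayRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in stays:
        counts[s.location_id] = counts.get(s.location_id, 0) + 1
    return counts


def radius_of_gyration(
    stays: Sequence[StayRecord], tess: WeightedSpatialTessellation
) -> float:
    """Visit-weighted RMS distance (km) of an agent's locations from their
    center of mass: ``r_g = sqrt(Σ_i p_i · d(l_i, l_cm)²)`` with
    ``p_i = n_i / Σ_k n_k`` and ``l_cm`` the p-weighted mean point."""
    counts = _visit_counts(stays)
    if not counts:
        raise ValueError("agent has no stays")
    if len(counts) == 1:
        return 0.0
    ids = list(counts)
    n = np.array([counts[i] for i in ids], dtype=float)
    p = n / n.sum()
    lats = np.array([tess.by_id(i).lat for i in ids])
    lons = np.array([tess.by_id(i).lon for i in ids])
    cm_lat = float(np.sum(p * lats))
    cm_lon = float(np.sum(p * lons))
    d = _haversine(np.radians(lats), np.radians(lons), np.radians(cm_lat), np.radians(cm_lon))
    return float(np.sqrt(np.sum(p * d**2)))


def mobility_entropy(stays: Sequence[StayRecord]) -> float:
    """Normalized Shannon entropy of visit frequencies, in [0, 1].

    ``S = −Σ p_i ln p_i / ln|L_u|``; defined as 0 for a single location.
    """
    counts = _visit_counts(stays)
    if not counts:
        raise ValueError("agent has no stays")
    if len(counts) == 1:
        return 0.0
    n = np.array(list(counts.values()), dtype=float)
    p = n / n.sum()
    return float(-np.sum(p * np.log(p)) / np.log(len(p)))


def population_measures(
    trajs: Sequence[SampledMobilityTrajectory],
    tess: WeightedSpatialTessellation,
    slot_seconds: int = 3600,
) -> MeasureSuite:
    """Compute all nine cohort distributions (see module docstring)."""
    if not trajs:
        raise ValueError("empty cohort")
    dmat = tess.distance_matrix()

    trip_distances: list[float] = []
    rgs: list[float] = []
    entropies: list[float] = []
    n_locations: list[int] = []
    stay_hours: list[float] = []
    trips_hour = np.zeros(24)
    trips_per_day: list[int] = []
    visits_by_location: dict[str, int] = {}
    rank_freq_sum = np.zeros(RANK_CUTOFF)
    rank_freq_n = np.zeros(RANK_CUTOFF)
    any_trips = False

    for traj in trajs:
        stays, trips = extract_stays_and_trips(traj)
        counts = _visit_counts(stays)
        rgs.append(radius_of_gyration(stays, tess))
        entropies.append(mobility_entropy(stays))
        n_locations.append(len(counts))
        for s in stays:
            stay_hours.append(s.length_slots * slot_seconds / 3600.0)
            visits_by_location[s.location_id] = visits_by_location.get(s.location_id, 0) + 1
        freqs = np.sort(np.array(list(counts.values()), dtype=float))[::-1]
        freqs /= freqs.sum()
        k = min(len(freqs), RANK_CUTOFF)
        rank_freq_sum[:k] += freqs[:k]
        rank_freq_n[:k] += 1

        day_counts: dict[int, int] = {}
        n_days = max(1, int(np.ceil(len(traj) * slot_seconds / 86400.0)))
        for origin, dest, arrival in trips:
            any_trips = True
            trip_distances.append(dmat[tess.index_of(origin), tess.index_of(dest)])
            hour = ((arrival - 1) * slot_seconds // 3600) % 24
            trips_hour[hour] += 1
            day = (arrival - 1) * slot_seconds // 86400
            day_counts[day] = day_counts.get(day, 0) + 1
        trips_per_day.extend(day_counts.get(d, 0) for d in range(n_days))

    dists: dict[str, EmpiricalDistribution] = {}
    dists["trip_distance"] = EmpiricalDistribution.from_values(
        trip_distances if any_trips else [0.0], _EDGES["trip_distance"]
    )
    dists["radius_of_gyration"] = EmpiricalDistribution.from_values(rgs, _EDGES["radius_of_gyration"])
    dists["entropy"] = EmpiricalDistribution.from_values(entropies, _EDGES["entropy"])
    mean_rank_freq = np.divide(
        rank_freq_sum, rank_freq_n, out=np.zeros(RANK_CUTOFF), where=rank_freq_n > 0
    )
    if mean_rank_freq.sum() == 0:
        mean_rank_freq[0] = 1.0
    dists["location_frequency"] = EmpiricalDistribution(
        tuple(_EDGES["location_frequency"]), tuple(mean_rank_freq / mean_rank_freq.sum())
    )
    dists["visits_per_location"] = EmpiricalDistribution.from_values(
        list(visits_by_location.values()), _EDGES["visits_per_location"]
    )
    dists["locations_per_user"] = EmpiricalDistribution.from_values(
        n_locations, _EDGES["locations_per_user"]
    )
    if trips_hour.sum() == 0:
        hour_probs = np.zeros(24)
        hour_probs[0] = 1.0
    else:
        hour_probs = trips_hour / trips_hour.sum()
    dists["trips_per_hour"] = EmpiricalDistribution(tuple(_EDGES["trips_per_hour"]), tuple(hour_probs))
    dists["trips_per_day"] = EmpiricalDistribution.from_values(trips_per_day, _EDGES["trips_per_day"])
    dists["stay_time"] = EmpiricalDistribution.from_values(stay_hours, _EDGES["stay_time"])
    return MeasureSuite(dists)


def _as_prob_arrays(y, yhat, check_edges: bool = True) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, EmpiricalDistribution) and isinstance(yhat, EmpiricalDistribution):
        if check_edges and not np.allclose(y.bin_edges, yhat.bin_edges):
            raise ValueError("distributions are binned on different edges")
        return np.asarray(y.probabilities), np.asarray(yhat.probabilities)
    ya, yb = np.asarray(y, dtype=float), np.asarray(yhat, dtype=float)
    if ya.shape != yb.shape:
        raise ValueError("vectors must have the same length")
    return ya, yb


def rmse(y, yhat) -> float:
    """Root mean square per-bin difference; symmetric in its arguments."""
    ya, yb = _as_prob_arrays(y, yhat)
    return float(np.sqrt(np.mean((ya - yb) ** 2)))


def kl_divergence(y, yhat, eps: float = KL_EPS) -> float:
    """KL(y‖ŷ) in nats after additive ε-smoothing and renormalization."""
    ya, yb = _as_prob_arrays(y, yhat)
    ya = (ya + eps) / (ya + eps).sum()
    yb = (yb + eps) / (yb + eps).sum()
    return float(np.sum(ya * np.log(ya / yb)))


def compare_suites(ref: MeasureSuite, syn: MeasureSuite) -> pd.DataFrame:
    """RMSE and KL for each measure: one row per measure, shaped like the
    per-model rows of a model-comparison table."""
    rows = [
        {
            "measure": name,
            "rmse": rmse(ref[name], syn[name]),
            "kl": kl_divergence(ref[name], syn[name]),
        }
        for name in MEASURE_NAMES
    ]
    return pd.DataFrame(rows).set_index("measure")


def plot_suite(suites: dict[str, MeasureSuite], path=None):
    """3×3 grid of the nine distributions, one line per named suite."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 3, figsize=(13, 10))
    log_measures = {"trip_distance", "radius_of_gyration", "visits_per_location", "stay_time"}
    for ax, name in zip(axes.flat, MEASURE_NAMES):
        for label, suite in suites.items():
            d = suite[name]
            centers = (np.asarray(d.bin_edges[:-1]) + np.asarray(d.bin_edges[1:])) / 2
            ax.plot(centers, d.probabilities, marker="o", ms=3, lw=1, label=label)
        ax.set_title(name)
        if name in log_measures:
            ax.set_xscale("log")
            ax.set_yscale("log")
    axes.flat[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
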