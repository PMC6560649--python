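"""Synthetic CDR corpora and toy tessellations with known ground truth.

Real call-detail records are proprietary, so this module plants a known
circadian routine — home at night, a work location on weekday-like day
hours, occasional heavy-tailed excursions elsewhere — and then observes it
through a sparse Poisson call process, producing CDR-shaped records whose
generating parameters are known exactly.  Every generator also returns the
ground truth (per-user home/work and the full latent occupancy), so
recovery experiments never have to re-derive it.

The planted routine depends only on the hour of the day, hence is periodic
under any period that is a multiple of a day (including the weekly period
the diary learner fits by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RawRecord
from .tessellation import Location, WeightedSpatialTessellation

__all__ = [
    "SynthSpec",
    "generate_toy_tessellation",
    "generate_synthetic_cdr",
    "NIGHT_HOURS",
    "DAY_HOURS",
]

# Planted schedule: night (home) hours, work-day hours; the rest are shoulder
# hours where the agent mixes home, work and excursions.
NIGHT_HOURS = frozenset(list(range(22, 24)) + list(range(0, 7)))
DAY_HOURS = frozenset(range(9, 18))
SHOULDER_HOME_PROB = 0.5
SHOULDER_WORK_PROB = 0.2
MAX_EXCURSION_SLOTS = 8


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for a synthetic CDR corpus."""

    n_users: int = 100
    n_locations: int = 50
    n_days: int = 28
    home_night_prob: float = 0.9
    work_day_prob: float = 0.8
    call_rate_per_hour: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("home_night_prob", "work_day_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_users, self.n_locations, self.n_days) < 1 or self.call_rate_per_hour <= 0:
            raise ValueError("counts and call rate must be positive")


def generate_toy_tessellation(
    m: int,
    seed: int = 0,
    zipf_exponent: float = 1.0,
    lat_range: tuple[float, float] = (43.0, 44.0),
    lon_range: tuple[float, float] = (10.0, 11.0),
    relevance_scale: float = 1000.0,
) -> WeightedSpatialTessellation:
    """Uniformly scattered locations with an exact Zipf rank–size relevance law.

    Relevances are ``scale · rank^(−s)`` assigned to locations in a random
    order, so a rank–size regression recovers slope −s exactly.
    """
    if m < 2:
        raise ValueError("need at least 2 locations")
    rng = np.random.default_rng(seed)
    lats = rng.uniform(*lat_range, size=m)
    lons = rng.uniform(*lon_range, size=m)
    while len({(a, b) for a, b in zip(lats, lons)}) < m:  # astronomically unlikely
        lats = rng.uniform(*lat_range, size=m)
        lons = rng.uniform(*lon_range, size=m)
    relevances = relevance_scale * (np.arange(1, m + 1, dtype=float)) ** (-zipf_exponent)
    rng.shuffle(relevances)
    width = len(str(m - 1))
    return WeightedSpatialTessellation(
        Location(f"L{i:0{width}d}", float(lats[i]), float(lons[i]), float(relevances[i]))
        for i in range(m)
    )


def _latent_occupancy(
    n_slots: int,
    home: str,
    work: str,
    others: list[str],
    spec: SynthSpec,
    rng: np.random.Generator,
) -> list[str]:
    symbols: list[str] = []
    excursion_left = 0
    excursion_loc = home
    for slot in range(n_slots):
        if excursion_left > 0:
            symbols.append(excursion_loc)
            excursion_left -= 1
            continue
        hour = slot % 24
        u = rng.random()
        if hour in NIGHT_HOURS:
            target = home if u < spec.home_night_prob else None
        elif hour in DAY_HOURS:
            target = work if u < spec.work_day_prob else None
        else:
            if u < SHOULDER_HOME_PROB:
                target = home
            elif u < SHOULDER_HOME_PROB + SHOULDER_WORK_PROB:
                target = work
            else:
                target = None
        if target is None:  # start a heavy-tailed excursion
            excursion_loc = others[int(rng.integers(len(others)))]
            duration = min(1 + int(rng.pareto(1.5)), MAX_EXCURSION_SLOTS)
            symbols.append(excursion_loc)
            excursion_left = duration - 1
        else:
            symbols.append(target)
    return symbols


def generate_synthetic_cdr(
    spec: SynthSpec,
    tess: WeightedSpatialTessellation,
) -> tuple[dict[str, list[RawRecord]], dict]:
    """CDR-shaped records with a planted routine, plus the ground truth.

    Per user: home and work are drawn relevance-proportionally (work ≠
    home); the latent hourly occupancy follows the planted schedule; the
    observed records thin the latent sequence with a Poisson call process of
    ``call_rate_per_hour``.  Returns ``(records_by_user, truth)`` where
    ``truth`` holds each user's home, work and full latent occupancy, plus
    the spec's probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n_slots = spec.n_days * 24
    ids = tess.ids
    p_rel = tess.relevances / tess.relevances.sum()

    records_by_user: dict[str, list[RawRecord]] = {}
    truth: dict = {
        "home_night_prob": spec.home_night_prob,
        "work_day_prob": spec.work_day_prob,
        "slot_seconds": 3600,
        "n_slots": n_slots,
        "users": {},
    }
    for u in range(spec.n_users):
        user = f"u{u:04d}"
        home = ids[int(rng.choice(len(ids), p=p_rel))]
        work = home
        while work == home:
            work = ids[int(rng.choice(len(ids), p=p_rel))]
        others = [i for i in ids if i != home]
        occupancy = _latent_occupancy(n_slots, home, work, others, spec, rng)

        recs: list[RawRecord] = []
        for slot, loc in enumerate(occupancy):
            n_calls = rng.poisson(spec.call_rate_per_hour)
            for _ in range(n_calls):
                ts = (slot + rng.random()) * 3600.0
                recs.append(RawRecord(ts, user, loc))
        recs.sort(key=lambda r: r.timestamp)
        records_by_user[user] = recs
        truth["users"][user] = {"home": home, "work": work, "occupancy": occupancy}
    return records_by_user, truth
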