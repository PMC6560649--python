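"""Mobility Diary Learner: fit a periodic Markov diary model from records.

The learner turns raw per-user location records into *abstract trajectories*
(one location symbol per time slot, geography stripped), estimates each
user's typical (home) location, and tallies a population-level Markov chain
over ``2 × N_period`` states ``(h, R)``: ``h`` is the slot within the period
(default one week of hourly slots, N_period = 168) and ``R`` flags whether
the user is at her typical location.  Four transition types exist:

* ``(h, 1) → (h+1, 1)``   — continue the routine one slot;
* ``(h, 1) → (h+τ, 0)``   — break the routine: leave home for a non-typical
  stay of exactly τ slots;
* ``(h, 0) → (h+1, 1)``   — return to the routine at the next slot;
* ``(h, 0) → (h+τ, 0)``   — move to a *different* non-typical location and
  stay τ slots.

All probabilities are empirical frequencies — the model is non-parametric.
Slot arithmetic is modulo N_period, so multi-week data accumulate into one
weekly profile.  Walking the fitted chain emits mobility diaries whose
circadian structure mirrors the training population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diary import MobilityDiary, TypicalDiary, parse_diary

__all__ = [
    "AbstractTrajectory",
    "MarkovDiaryModel",
    "abstractify",
    "estimate_typical_diary",
    "fit_markov",
    "md_generate",
    "diary_to_abstract",
    "hourly_move_profile",
]

State = tuple[int, int]  # (slot-of-period h, routine flag R)


@dataclass(frozen=True)
class AbstractTrajectory:
    """Per-slot abstract location symbols for one user (no coordinates)."""

    symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.symbols)


def abstractify(
    records: Sequence[tuple[float, str]],
    slot_seconds: int,
    start: float | None = None,
    n_slots: int | None = None,
) -> AbstractTrajectory:
    """Assign one abstract location to every time slot of a user's span.

    ``records`` are time-ordered ``(timestamp, location_id)`` pairs.  Slot i
    covers ``[start + i·t, start + (i+1)·t)``.  The slot's symbol is the
    location observed most often within it; ties go to the location with the
    highest overall frequency in the user's records, then to the
    lexicographically smaller id.  Slots with no observation inherit the
    previous slot's symbol (no movement assumed); leading empty slots are
    backfilled from the first observed location.
    """
    if not records:
        raise ValueError("no records for user")
    times = np.array([r[0] for r in records], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("records must be sorted by timestamp")
    if start is None:
        start = float(times[0])
    if n_slots is None:
        n_slots = int((times[-1] - start) // slot_seconds) + 1

    overall: dict[str, int] = {}
    for _, loc in records:
        overall[loc] = overall.get(loc, 0) + 1

    per_slot: list[dict[str, int]] = [dict() for _ in range(n_slots)]
    for ts, loc in records:
        i = int((ts - start) // slot_seconds)
        if 0 <= i < n_slots:
            per_slot[i][loc] = per_slot[i].get(loc, 0) + 1

    symbols: list[str | None] = [None] * n_slots
    for i, counts in enumerate(per_slot):
        if counts:
            # (slot count, overall count) descending, then id ascending
            symbols[i] = min(counts, key=lambda l: (-counts[l], -overall[l], l))
    if all(s is None for s in symbols):
        raise ValueError("no records fall inside the requested span")
    first = next(s for s in symbols if s is not None)
    prev = first
    for i in range(n_slots):
        if symbols[i] is None:
            symbols[i] = prev
        else:
            prev = symbols[i]
    return AbstractTrajectory(tuple(symbols))  # type: ignore[arg-type]


def estimate_typical_diary(traj: AbstractTrajectory) -> TypicalDiary:
    """Home = the most frequent symbol of the trajectory (ties → smaller id)."""
    counts: dict[str, int] = {}
    for s in traj.symbols:
        counts[s] = counts.get(s, 0) + 1
    home = min(counts, key=lambda l: (-counts[l], l))
    return TypicalDiary(n_slots=len(traj), home_symbol=home)


class MarkovDiaryModel:
    """Periodic 2N-state Markov diary model with empirical transition rows.

    ``transitions`` maps an observed from-state ``(h, R)`` to a dict of
    to-states with probabilities summing to 1.  States never observed in the
    training data have no row; the walker falls back to a deterministic
    return home ``(h, ·) → (h+1, 1)`` and warns.
    """

    def __init__(
        self,
        transitions: dict[State, dict[State, float]],
        n_period: int = 168,
        slot_seconds: int = 3600,
    ):
        if n_period < 2:
            raise ValueError("n_period must be >= 2")
        for s, row in transitions.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"row {s} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"row {s} has a negative probability")
        self.transitions = transitions
        self.n_period = n_period
        self.slot_seconds = slot_seconds

    def prob(self, s: State, s2: State) -> float:
        return self.transitions.get(s, {}).get(s2, 0.0)

    # -- serialization: flat CSV with a small comment header ----------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# N_period={self.n_period}\n")
            fh.write(f"# slot_seconds={self.slot_seconds}\n")
            fh.write("h_from,R_from,h_to,R_to,prob\n")
            for (h, r), row in sorted(self.transitions.items()):
                for (h2, r2), p in sorted(row.items()):
                    fh.write(f"{h},{r},{h2},{r2},{p!r}\n")

    @classmethod
    def from_csv(cls, path) -> "MarkovDiaryModel":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = int(val)
                body_start += 1
            else:
                break
        df = pd.read_csv(path, skiprows=body_start)
        transitions: dict[State, dict[State, float]] = {}
        for row in df.itertuples(index=False):
            s = (int(row.h_from), int(row.R_from))
            transitions.setdefault(s, {})[(int(row.h_to), int(row.R_to))] = float(row.prob)
        return cls(
            transitions,
            n_period=meta.get("N_period", 168),
            slot_seconds=meta.get("slot_seconds", 3600),
        )


def _run_end(symbols: Sequence[str], x: int) -> int:
    """Index of the last slot of the maximal equal-symbol run containing x."""
    j = x
    n = len(symbols)
    while j + 1 < n and symbols[j + 1] == symbols[j]:
        j += 1
    return j


def fit_markov(
    corpus: Iterable[tuple[AbstractTrajectory, TypicalDiary]],
    n_period: int = 168,
    slot_seconds: int = 3600,
) -> MarkovDiaryModel:
    """Tally the four transition types over a population of trajectories.

    Every *chain event* position contributes exactly one transition, so each
    observed row is a probability distribution by construction.  Event
    positions are: every slot at the typical location, and the final slot of
    every non-typical stay.  Mid-stay non-typical slots are not events (the
    chain jumps over them in one τ-slot transition).  Stays longer than
    ``n_period − 1`` slots are right-censored into that cap; a stay still
    running when the trajectory ends has an unobserved length and is dropped
    from the tally (counting its truncated length would pile spurious short
    stays onto the period position where trajectories happen to end).
    """
    tau_max = n_period - 1
    counts: dict[State, dict[State, int]] = {}

    def record(s: State, s2: State) -> None:
        counts.setdefault(s, {})
        counts[s][s2] = counts[s].get(s2, 0) + 1

    n_trajs = 0
    for traj, typical in corpus:
        n_trajs += 1
        a = traj.symbols
        n = len(a)
        if n < 2:
            raise ValueError("trajectories must have at least 2 slots")
        home = typical.home_symbol
        d = [s == home for s in a]
        x = 0
        while x < n - 1:
            h = x % n_period
            if d[x]:
                if d[x + 1]:
                    record((h, 1), ((h + 1) % n_period, 1))
                    x += 1
                else:
                    end = _run_end(a, x + 1)
                    if end < n - 1:  # stay end observed
                        tau = min(end - x, tau_max)
                        record((h, 1), ((h + tau) % n_period, 0))
                    x = end
            else:
                if x == _run_end(a, x):  # stay ends here: this is an event
                    if d[x + 1]:
                        record((h, 0), ((h + 1) % n_period, 1))
                        x += 1
                    else:
                        end = _run_end(a, x + 1)
                        if end < n - 1:
                            tau = min(end - x, tau_max)
                            record((h, 0), ((h + tau) % n_period, 0))
                        x = end
                else:  # mid-stay: not a chain event
                    x = _run_end(a, x)
    if n_trajs == 0:
        raise ValueError("empty corpus")

    transitions: dict[State, dict[State, float]] = {}
    for s, row in counts.items():
        total = sum(row.values())
        transitions[s] = {s2: c / total for s2, c in row.items()}
    return MarkovDiaryModel(transitions, n_period=n_period, slot_seconds=slot_seconds)


def md_generate(
    model: MarkovDiaryModel,
    n_slots: int,
    rng: np.random.Generator,
    start_state: State = (0, 1),
) -> MobilityDiary:
    """Emit a mobility diary by walking the fitted chain from ``start_state``.

    Routine transitions append ``1``; a routine break appends ``|`` followed
    by τ ``0`` slots; a return appends ``|1``.  The walk stops once the
    diary reaches ``n_slots`` (the last stay is truncated if necessary).
    Undefined rows fall back to a deterministic return home, with a warning.
    """
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    P = model.n_period
    h, r = start_state
    parts: list[str] = ["1" if r == 1 else "0"]
    emitted = 1
    warned = False
    while emitted < n_slots:
        row = model.transitions.get((h, r))
        if row is None:
            if not warned:
                warnings.warn(
                    f"state (h={h}, R={r}) has no observed transitions; "
                    "falling back to a deterministic return home",
                    stacklevel=2,
                )
                warned = True
            h2, r2 = (h + 1) % P, 1
        else:
            keys = list(row.keys())
            cum = np.cumsum([row[k] for k in keys])
            h2, r2 = keys[min(int(np.searchsorted(cum, rng.random() * cum[-1], side="right")), len(keys) - 1)]
        if r2 == 1:
            parts.append("1" if r == 1 else "|1")
            emitted += 1
        else:
            tau = (h2 - h) % P
            tau = min(tau if tau > 0 else P, n_slots - emitted)
            parts.append("|" + "0" * tau)
            emitted += tau
        h, r = h2, r2
    return parse_diary("".join(parts))


def diary_to_abstract(
    diary: MobilityDiary, home_symbol: str = "home", away_prefix: str = "away"
) -> AbstractTrajectory:
    """Expand a diary back into abstract symbols, one fresh symbol per 0-run.

    Routine slots map to ``home_symbol``; each non-routine segment gets its
    own placeholder symbol, so consecutive non-typical stays differ — the
    exact inverse of :func:`ditras.diary.diary_from_abstract` up to symbol
    names.  Used to refit a chain from diaries it generated.
    """
    symbols: list[str] = []
    k = 0
    for seg in diary.segments:
        if seg.routine:
            symbols.extend([home_symbol] * seg.length)
        else:
            symbols.extend([f"{away_prefix}{k}"] * seg.length)
            k += 1
    return AbstractTrajectory(tuple(symbols))


def hourly_move_profile(
    model: MarkovDiaryModel,
    n_slots: int,
    n_diaries: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo per-hour-of-day move probability of the chain (24 bins).

    Samples diaries from the chain and histograms the arrival slots of their
    segments (every separator is a move) by hour of day, normalized to a
    probability vector.  This is the chain-side profile that a cohort's
    trips-per-hour distribution should reproduce.
    """
    counts = np.zeros(24)
    for _ in range(n_diaries):
        diary = md_generate(model, n_slots, rng)
        for seg in diary.segments[1:]:
            hour = (seg.start_slot * model.slot_seconds // 3600) % 24
            counts[hour] += 1
    if counts.sum() == 0:
        raise ValueError("chain produced no moves")
    return counts / counts.sum()
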