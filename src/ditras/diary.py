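"""Mobility diaries: the 1/0/| grammar and the RD and WT baseline generators.

A mobility diary is a string over the alphabet ``{1, 0, |}`` describing an
agent's schedule one time slot at a time: ``1`` means the agent is at the
typical (home) location of her routine, ``0`` means she is at some other
location, and ``|`` marks a trip between two *different* locations.  Two
adjacent equal symbols without a separator mean the agent stayed put, so a
separator is required exactly where the location changes: between a ``1`` and
a ``0`` (home versus elsewhere), and optionally between two ``0`` runs
(different non-typical locations).  ``1|1`` is ill-formed — home to home is
not a trip.

Two baseline diary generators live here.  RD ("random diary") moves every
slot.  WT ("waiting time") draws stay durations from the truncated power law
P(Δt) ∝ Δt^(−1−β) · exp(−Δt/τ) with β = 0.8 and τ = 17 hours; it reproduces
realistic waiting times but no circadian rhythm, so like RD its diaries
contain no routine (``1``) slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "DiaryParseError",
    "Segment",
    "MobilityDiary",
    "TypicalDiary",
    "WTParams",
    "parse_diary",
    "diary_from_abstract",
    "rd_generate",
    "wt_generate",
    "wt_stay_pmf",
    "sample_wt_durations",
    "read_diaries",
    "write_diaries",
]


class DiaryParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class Segment:
    """A maximal stay: ``length`` consecutive slots at one location."""

    start_slot: int
    length: int
    routine: bool


@dataclass(frozen=True)
class MobilityDiary:
    """A validated diary string with its segment decomposition."""

    text: str
    n_slots: int
    segments: tuple[Segment, ...]

    @property
    def routine_flags(self) -> list[int]:
        """Per-slot indicator: 1 if the slot is at the typical location."""
        return [1 if c == "1" else 0 for c in self.text if c != "|"]

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class TypicalDiary:
    """The routine template: one home symbol occupying every slot."""

    n_slots: int
    home_symbol: str

    def __post_init__(self):
        if self.n_slots < 1:
            raise ValueError("typical diary needs at least one slot")


@dataclass(frozen=True)
class WTParams:
    """Waiting-time law parameters: P(Δt) ∝ Δt^(−1−beta) exp(−Δt/tau)."""

    beta: float = 0.8
    tau_hours: float = 17.0

    def __post_init__(self):
        if self.beta <= 0 or self.tau_hours <= 0:
            raise ValueError("beta and tau_hours must be positive")


def parse_diary(text: str) -> MobilityDiary:
    """Validate a diary string and decompose it into maximal stays.

    Raises :class:`DiaryParseError` (with the offending position) on grammar
    violations: characters outside {1,0,|}, leading/trailing/doubled
    separators, a 0 adjacent to a 1 without a separator, or a separator
    between two 1 characters.
    """
    if not text:
        raise DiaryParseError("empty diary", 0)
    for pos, c in enumerate(text):
        if c not in "10|":
            raise DiaryParseError(f"invalid character {c!r}", pos)
    if text[0] == "|":
        raise DiaryParseError("diary starts with a separator", 0)
    if text[-1] == "|":
        raise DiaryParseError("diary ends with a separator", len(text) - 1)
    for pos in range(len(text) - 1):
        a, b = text[pos], text[pos + 1]
        if a == "|" and b == "|":
            raise DiaryParseError("adjacent separators", pos + 1)
        if {a, b} == {"0", "1"}:
            raise DiaryParseError("location change without separator", pos + 1)
    for pos in range(1, len(text) - 1):
        if text[pos] == "|" and text[pos - 1] == "1" and text[pos + 1] == "1":
            raise DiaryParseError("separator between two routine slots", pos)

    segments: list[Segment] = []
    slot = 0
    i = 0
    while i < len(text):
        if text[i] == "|":
            i += 1
            continue
        c = text[i]
        j = i
        while j < len(text) and text[j] == c:
            j += 1
        segments.append(Segment(start_slot=slot, length=j - i, routine=c == "1"))
        slot += j - i
        i = j
    return MobilityDiary(text=text, n_slots=slot, segments=tuple(segments))


def diary_from_abstract(symbols: Sequence[str], typical: TypicalDiary) -> MobilityDiary:
    """Encode an abstract trajectory against a typical diary.

    Slot i is ``1`` iff the abstract location equals the home symbol; a
    separator is inserted exactly where the abstract location changes
    between consecutive slots.
    """
    if len(symbols) != typical.n_slots:
        raise ValueError(
            f"abstract trajectory has {len(symbols)} slots, typical diary {typical.n_slots}"
        )
    home = typical.home_symbol
    out: list[str] = []
    for i, sym in enumerate(symbols):
        if i > 0 and sym != symbols[i - 1]:
            out.append("|")
        out.append("1" if sym == home else "0")
    return parse_diary("".join(out))


def rd_generate(n_slots: int, rng: np.random.Generator | None = None) -> MobilityDiary:
    """Random Diary: a new location every slot — ``0|0|...|0``.

    ``rng`` is accepted for interface uniformity with the other generators;
    RD is deterministic in time (the randomness is entirely spatial).
    """
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    return parse_diary("|".join("0" * n_slots))


def _wt_grid(params: WTParams, slot_seconds: int, n: int = 4096):
    """Dense support grid and CDF of the truncated waiting-time density.

    Support is [one slot, 30·tau]: the lower bound makes every drawn stay
    representable as at least one slot; the upper bound truncates the
    exponential tail far beyond where it carries mass.
    """
    lo = slot_seconds / 3600.0
    hi = 30.0 * params.tau_hours
    grid = np.linspace(lo, hi, n)
    dens = grid ** (-1.0 - params.beta) * np.exp(-grid / params.tau_hours)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
    return grid, cdf / cdf[-1]


def sample_wt_durations(
    n: int, params: WTParams, slot_seconds: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` stay durations (hours) by inverse-CDF on a dense grid."""
    grid, cdf = _wt_grid(params, slot_seconds)
    return np.interp(rng.random(n), cdf, grid)


def wt_mean_duration(params: WTParams, slot_seconds: int) -> float:
    """Mean of the truncated waiting-time law in hours, by quadrature."""
    lo = slot_seconds / 3600.0
    hi = 30.0 * params.tau_hours
    dens = lambda x: x ** (-1.0 - params.beta) * np.exp(-x / params.tau_hours)
    z, _ = quad(dens, lo, hi)
    m, _ = quad(lambda x: x * dens(x), lo, hi)
    return m / z


def wt_stay_pmf(params: WTParams, slot_seconds: int, max_slots: int) -> np.ndarray:
    """Discrete stay-length law implied by flooring durations to whole slots.

    Entry k−1 is P(stay of k slots), k = 1..max_slots, i.e. the density mass
    on [k·t, (k+1)·t) (the last bin absorbs the remaining tail mass).
    """
    t_h = slot_seconds / 3600.0
    hi = 30.0 * params.tau_hours
    dens = lambda x: x ** (-1.0 - params.beta) * np.exp(-x / params.tau_hours)
    z, _ = quad(dens, t_h, hi)
    pmf = np.zeros(max_slots)
    for k in range(1, max_slots + 1):
        a = k * t_h
        b = (k + 1) * t_h if k < max_slots else hi
        if a >= hi:
            break
        mass, _ = quad(dens, a, min(b, hi))
        pmf[k - 1] = mass / z
    return pmf / pmf.sum()


def wt_generate(
    n_slots: int,
    params: WTParams = WTParams(),
    slot_seconds: int = 3600,
    rng: np.random.Generator | None = None,
) -> MobilityDiary:
    """Waiting-Time diary: i.i.d. heavy-tailed stays, no routine slots.

    Each drawn duration is floored to whole slots (the support lower bound
    of one slot guarantees at least one); the final stay is truncated so the
    diary is exactly ``n_slots`` long.
    """
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    runs: list[int] = []
    total = 0
    while total < n_slots:
        dur_h = float(sample_wt_durations(1, params, slot_seconds, rng)[0])
        k = max(1, int(dur_h * 3600.0 / slot_seconds))
        k = min(k, n_slots - total)
        runs.append(k)
        total += k
    return parse_diary("|".join("0" * k for k in runs))


def read_diaries(path) -> list[MobilityDiary]:
    """One diary string per line; '#' lines are comments."""
    diaries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                diaries.append(parse_diary(line))
    return diaries


def write_diaries(diaries: Sequence[MobilityDiary], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for d in diaries:
            fh.write(d.text + "\n")
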