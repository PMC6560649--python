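"""The simulation engine: compose a diary generator with a trajectory
generator over a tessellation and emit sampled mobility trajectories.

For every agent the engine (i) draws a mobility diary of N slots, (ii)
assigns the agent's home by relevance-proportional sampling, and (iii)
translates the diary into physical locations: routine (``1``) slots emit the
home location; each non-routine (``0``) run triggers exactly one
trajectory-generator call whose result must differ from both the home and
the immediately preceding location, and the chosen location fills the whole
run.  Travel time is treated as negligible — each slot belongs wholly to one
location.

Reproducibility: each agent has an independent RNG substream keyed by
``(seed, agent_id)``, so cohorts are bit-identical under a fixed seed and
independent of agent execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .diary import MobilityDiary, TypicalDiary, WTParams, rd_generate, wt_generate
from .mdl import MarkovDiaryModel, md_generate
from .tessellation import (
    Location,
    ODMatrix,
    WeightedSpatialTessellation,
    build_od_matrix,
    sample_by_relevance,
)
from .trajgen import AgentState, DEPRParams, SWIMParams, depr_choose, latp_choose, swim_choose

__all__ = [
    "SampledMobilityTrajectory",
    "SimulationConfig",
    "LocatedTypicalDiary",
    "assign_home",
    "run_ditras",
    "trajectories_to_dataframe",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "DIARY_GENERATORS",
    "TRAJECTORY_GENERATORS",
]

MAX_REDRAWS = 100

DIARY_GENERATORS = ("md", "rd", "wt")
TRAJECTORY_GENERATORS = ("depr", "swim", "latp")


@dataclass(frozen=True)
class SampledMobilityTrajectory:
    """Per-slot physical locations of one agent; slots run 1..N."""

    agent_id: int
    entries: tuple[tuple[float, float, int, str], ...]  # (lat, lon, slot, location_id)

    @property
    def location_ids(self) -> list[str]:
        return [e[3] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LocatedTypicalDiary:
    """A typical diary whose abstract home has been pinned to a location."""

    n_slots: int
    home: Location


@dataclass
class SimulationConfig:
    n_agents: int
    n_slots: int
    slot_seconds: int = 3600
    seed: int = 0
    diary: str = "md"
    traj: str = "depr"
    rho: float = 0.6
    gamma: float = 0.21
    alpha: float = 0.75
    wt_beta: float = 0.8
    wt_tau_hours: float = 17.0

    def __post_init__(self):
        if self.n_agents < 1 or self.n_slots < 1:
            raise ValueError("n_agents and n_slots must be >= 1")
        if self.diary not in DIARY_GENERATORS:
            raise ValueError(f"unknown diary generator {self.diary!r}; choose from {DIARY_GENERATORS}")
        if self.traj not in TRAJECTORY_GENERATORS:
            raise ValueError(
                f"unknown trajectory generator {self.traj!r}; choose from {TRAJECTORY_GENERATORS}"
            )


def assign_home(
    typical: TypicalDiary | int,
    tess: WeightedSpatialTessellation,
    rng: np.random.Generator,
) -> LocatedTypicalDiary:
    """Pin the typical diary's home to a relevance-proportional location."""
    n_slots = typical if isinstance(typical, int) else typical.n_slots
    return LocatedTypicalDiary(n_slots=n_slots, home=sample_by_relevance(tess, rng))


def _diary_factory(cfg: SimulationConfig, model: MarkovDiaryModel | None):
    if cfg.diary == "md":
        if model is None:
            raise ValueError("diary generator 'md' needs a fitted MarkovDiaryModel")
        return lambda n, rng: md_generate(model, n, rng)
    if cfg.diary == "rd":
        return lambda n, rng: rd_generate(n, rng)
    params = WTParams(beta=cfg.wt_beta, tau_hours=cfg.wt_tau_hours)
    return lambda n, rng: wt_generate(n, params, cfg.slot_seconds, rng)


def _chooser_factory(
    cfg: SimulationConfig,
    tess: WeightedSpatialTessellation,
    od: ODMatrix | None,
) -> Callable[[AgentState, np.random.Generator], Location]:
    if cfg.traj == "depr":
        if od is None:
            od = build_od_matrix(tess)
        params = DEPRParams(rho=cfg.rho, gamma=cfg.gamma)
        return lambda agent, rng: depr_choose(agent, od, params, rng)
    if cfg.traj == "swim":
        params = SWIMParams(alpha=cfg.alpha)
        return lambda agent, rng: swim_choose(agent, tess, params, rng)
    return lambda agent, rng: latp_choose(agent, tess, rng=rng)


def run_ditras(
    cfg: SimulationConfig,
    tess: WeightedSpatialTessellation,
    model: MarkovDiaryModel | None = None,
    od: ODMatrix | None = None,
) -> list[SampledMobilityTrajectory]:
    """Simulate a cohort of agents; returns one trajectory per completed agent.

    An agent whose location choice keeps violating the engine constraints
    (next location must differ from home and from the previous location)
    after ``MAX_REDRAWS`` redraws is aborted with a warning; the run
    continues with the remaining agents.
    """
    diary_gen = _diary_factory(cfg, model)
    chooser = _chooser_factory(cfg, tess, od)
    out: list[SampledMobilityTrajectory] = []
    for agent_id in range(cfg.n_agents):
        rng = np.random.default_rng([cfg.seed, agent_id])
        try:
            out.append(_simulate_agent(agent_id, cfg, tess, diary_gen, chooser, rng))
        except Exception as exc:  # noqa: BLE001 — isolate per-agent failures
            warnings.warn(f"agent {agent_id} aborted: {exc}", stacklevel=2)
    return out


def _simulate_agent(
    agent_id: int,
    cfg: SimulationConfig,
    tess: WeightedSpatialTessellation,
    diary_gen,
    chooser,
    rng: np.random.Generator,
) -> SampledMobilityTrajectory:
    diary: MobilityDiary = diary_gen(cfg.n_slots, rng)
    located = assign_home(cfg.n_slots, tess, rng)
    home_idx = tess.index_of(located.home.id)
    agent = AgentState(tess=tess, current=home_idx, home=home_idx, visit_counts={home_idx: 1})

    entries: list[tuple[float, float, int, str]] = []
    slot = 1
    for seg_i, seg in enumerate(diary.segments):
        if seg.routine:
            loc = located.home
            if not (seg_i == 0):  # returning home is a fresh visit; the start is pre-counted
                agent.record_visit(home_idx)
            agent.current = home_idx
        else:
            prev = agent.current
            loc = None
            for _ in range(MAX_REDRAWS):
                cand = chooser(agent, rng)
                ci = tess.index_of(cand.id)
                if ci != home_idx and ci != prev:
                    loc = cand
                    break
            if loc is None:
                raise RuntimeError(
                    f"no admissible location after {MAX_REDRAWS} redraws "
                    f"(must differ from home {located.home.id!r} and previous)"
                )
            agent.record_visit(tess.index_of(loc.id))
        for _ in range(seg.length):
            entries.append((loc.lat, loc.lon, slot, loc.id))
            slot += 1
    return SampledMobilityTrajectory(agent_id=agent_id, entries=tuple(entries))


def trajectories_to_dataframe(trajs: Sequence[SampledMobilityTrajectory]) -> pd.DataFrame:
    rows = [
        (t.agent_id, slot, loc_id, lat, lon)
        for t in trajs
        for (lat, lon, slot, loc_id) in t.entries
    ]
    return pd.DataFrame(rows, columns=["agent_id", "slot", "location_id", "lat", "lon"])


def write_trajectories_csv(trajs: Sequence[SampledMobilityTrajectory], path) -> None:
    trajectories_to_dataframe(trajs).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[SampledMobilityTrajectory]:
    df = pd.read_csv(path, dtype={"location_id": str}, float_precision="round_trip")
    out = []
    for agent_id, grp in df.groupby("agent_id", sort=True):
        grp = grp.sort_values("slot")
        entries = tuple(
            (float(r.lat), float(r.lon), int(r.slot), r.location_id)
            for r in grp.itertuples(index=False)
        )
        out.append(SampledMobilityTrajectory(agent_id=int(agent_id), entries=entries))
    return out
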