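"""Location-choice mechanisms: d-EPR, SWIM and LATP.

Each chooser answers one question — given an agent's state and the
tessellation, which location does she visit next? — and never proposes the
current location.

* **d-EPR** (density-Exploration and Preferential Return): with probability
  ``p_new = ρ·N^(−γ)`` (N = distinct locations visited so far; ρ = 0.6,
  γ = 0.21) the agent *explores* an unvisited location drawn from the
  gravity row of her current location; otherwise she *returns* to a visited
  location with probability proportional to her past visit counts.
* **SWIM**: weight ``α/(1+dist(home, L))² + (1−α)·r̂(L)`` with α = 0.75 and
  relevance max-rescaled to [0, 1]; distance is measured from home, and
  there is no preferential return.
* **LATP** (least-action trip planning): weight ``dist(current, L)^(−1.5)``;
  distance only, no relevance, no preferential return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tessellation import Location, ODMatrix, WeightedSpatialTessellation

__all__ = [
    "AgentState",
    "DEPRParams",
    "SWIMParams",
    "exploration_probability",
    "depr_choose",
    "swim_choose",
    "latp_choose",
]


@dataclass
class DEPRParams:
    """Exploration-probability constants of the EPR family."""

    rho: float = 0.6
    gamma: float = 0.21

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SWIMParams:
    alpha: float = 0.75

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class AgentState:
    """Where an agent is, where she lives, and what she has visited.

    ``visit_counts`` counts arrivals (one per maximal stay) per location
    index; ``n_distinct`` is the size of its support.
    """

    tess: WeightedSpatialTessellation
    current: int
    home: int
    visit_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return len(self.visit_counts)

    def record_visit(self, loc_index: int) -> None:
        self.visit_counts[loc_index] = self.visit_counts.get(loc_index, 0) + 1
        self.current = loc_index


def exploration_probability(n_distinct: int, params: DEPRParams = DEPRParams()) -> float:
    """``p_new = rho · N^(−gamma)`` — decreasing in the locations seen so far."""
    if n_distinct < 1:
        raise ValueError("agent must have visited at least one location")
    return params.rho * n_distinct ** (-params.gamma)


def _sample_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(weights)
    if cum[-1] <= 0:
        raise ValueError("no candidate location has positive weight")
    return min(int(np.searchsorted(cum, rng.random() * cum[-1], side="right")), len(weights) - 1)


def depr_choose(
    agent: AgentState,
    od: ODMatrix,
    params: DEPRParams = DEPRParams(),
    rng: np.random.Generator | None = None,
) -> Location:
    """Explore an unvisited location via the gravity row, or return.

    The exploration candidate set is the *unvisited* locations other than the
    current one, with the current location's gravity row renormalized over
    them; the return candidate set is the visited locations other than the
    current one, weighted by visit counts.  A branch with no candidates
    falls through to the other; if both are empty the choice is impossible.
    """
    if rng is None:
        rng = np.random.default_rng()
    if agent.n_distinct < 1:
        raise ValueError("agent must have visited at least one location")
    m = len(od.ids)
    visited = np.zeros(m, dtype=bool)
    for i in agent.visit_counts:
        visited[i] = True

    explore_w = od.row(agent.current).copy()
    explore_w[visited] = 0.0
    explore_w[agent.current] = 0.0
    return_w = np.zeros(m)
    for i, c in agent.visit_counts.items():
        return_w[i] = c
    return_w[agent.current] = 0.0

    explore_ok = explore_w.sum() > 0
    return_ok = return_w.sum() > 0
    if not explore_ok and not return_ok:
        raise ValueError("no eligible location: everything is either current or unreachable")

    p_new = exploration_probability(agent.n_distinct, params)
    explore = rng.random() < p_new
    if explore and not explore_ok:
        explore = False
    elif not explore and not return_ok:
        explore = True
    weights = explore_w if explore else return_w
    return agent.tess[_sample_index(weights, rng)]


def swim_choose(
    agent: AgentState,
    tess: WeightedSpatialTessellation,
    params: SWIMParams = SWIMParams(),
    rng: np.random.Generator | None = None,
) -> Location:
    """Sample the next location by home-distance and rescaled relevance."""
    if rng is None:
        rng = np.random.default_rng()
    d_home = tess.distance_matrix()[agent.home]
    r_hat = tess.relevances / tess.relevances.max()
    w = params.alpha / (1.0 + d_home) ** 2 + (1.0 - params.alpha) * r_hat
    w = w.copy()
    w[agent.current] = 0.0
    return tess[_sample_index(w, rng)]


def latp_choose(
    agent: AgentState,
    tess: WeightedSpatialTessellation,
    exponent: float = 1.5,
    rng: np.random.Generator | None = None,
) -> Location:
    """Sample the next location with weight ``dist(current, L)^(−exponent)``."""
    if rng is None:
        rng = np.random.default_rng()
    d = tess.distance_matrix()[agent.current].copy()
    w = np.zeros(len(tess))
    mask = np.arange(len(tess)) != agent.current
    w[mask] = d[mask] ** (-exponent)
    return tess[_sample_index(w, rng)]
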