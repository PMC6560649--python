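# Methods

This note documents the modelling assumptions, numerical conventions and
design choices behind the package, in the spirit of a model-description
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time, space and the diary grammar

Time is discretised into slots of `t` seconds (default 3600); each slot
belongs wholly to one location — travel time is treated as negligible.
Space is a *weighted spatial tessellation*: locations identified by their
centroid coordinates, each with a positive relevance weight (calls served,
stops recorded, or population density).  Only centroids are used; polygon
geometry is out of scope.  Distances are great-circle (haversine) with
Earth radius 6371.0 km.  Relevance is accepted as any positive real, not an
integer count, so population-density proxies are admissible; zero relevance
and coincident centroids are rejected at load time (a zero distance would
give an unbounded gravity weight).

A mobility diary is a string over `{1, 0, |}`.  Validity rules: no leading,
trailing or doubled separators; a separator is *required* between a `1` and
a `0` (the location changes) and *forbidden* between two `1`s (home-to-home
is not a trip); between two `0` runs it distinguishes one stay from two.
The diary string is the canonical serialization; segment decompositions are
derived, never stored.

## The diary learner

Raw records are first *abstractified*: one location symbol per slot — the
single observed location, else the most frequent within the slot, ties
broken by the user's highest overall frequency and then by smaller id
(fully deterministic); empty slots inherit the previous symbol (no movement
assumed) and leading empty slots backfill from the first observation.  The
typical diary is the simplest possible routine: the user's single most
frequent symbol (her home) occupying every slot.  Richer multi-location
routines are a deliberate non-goal.

The diary model is a Markov chain over `2·N_period` states `(h, R)`.  The
period defaults to one week of slots (168 at hourly resolution) — weekly
regularity is the natural cycle of the routine — and slot arithmetic is
modulo the period, so months of data accumulate into one weekly profile.
Estimation is a pure frequency tally over *chain events*: every slot spent
at the typical location is an event (continue or break), and the final slot
of every non-typical stay is an event (return or move on).  Mid-stay slots
are not events — the chain jumps a τ-slot stay in one transition — and
normalising over events is what makes each row a probability distribution.
Two censoring rules: stays longer than `N_period − 1` slots are capped
there, and a stay still running when a trajectory ends is dropped entirely,
because its true length is unobserved and counting the truncated length
would concentrate spurious short stays at the period position where
trajectories happen to end.

One population-level chain is fitted, not per-user chains.  States never
observed get no row; at generation time the walker falls back to a
deterministic return home and warns.  No smoothing is applied — the model
is intentionally non-parametric.  Walks start at `(h=0, R=1)` (home at
period start, configurable).

## Baseline diary generators

RD moves every slot (`0|0|…|0`).  WT draws stay durations from
`P(Δt) ∝ Δt^(−1−β) e^(−Δt/τ)` with β = 0.8 and τ = 17 hours, by inverse
CDF on a dense trapezoid-integrated grid.  The law's support is
`[one slot, 30·τ]`: the lower bound makes every stay representable after
flooring to whole slots, the upper bound truncates the exponential tail
where it carries no appreciable mass.  Durations are floored to whole
slots; the final stay is truncated to land the diary exactly on the
requested length.  Neither baseline has a home concept, so their diaries
contain no `1` slots — which is why home-conditioned measures are
meaningless for them.

## Trajectory generators

All three choosers operate on the candidate set "every tessellation
location except the current one" and never return the current location.

*d-EPR.*  Exploration probability `p_new = ρ N^(−γ)` with ρ = 0.6,
γ = 0.21.  Exploration is restricted to *unvisited* locations, sampling
the gravity row of the current location renormalised over them; the
gravity matrix is `p_ij = (1/Z) r_i r_j / d_ij²` with a single joint
normalisation Z (deterrence exponent fixed at 2).  Row-conditional
renormalisation — rather than joint-matrix sampling — is the package's
reading of "select according to p_ij" given a current location.  Return
picks a previously visited location with probability proportional to past
visit counts, where a *visit* is one arrival (one maximal stay).  If every
location has been visited the return branch is used regardless of the coin
flip, and vice versa.

*SWIM.*  Weight `α · (1 + d(home, L))^(−2) + (1 − α) · r̂(L)`, α = 0.75.
The relevance term is max-rescaled to [0, 1] before mixing: the distance
term is bounded by 1, and mixing it with an unbounded raw relevance would
make α meaningless.  This rescaling is a package convention.

*LATP.*  Weight `d(current, L)^(−1.5)`; no relevance, no return mechanism.

## The engine

Per agent: draw a diary, assign the home by relevance-proportional
sampling, then translate.  `1`-slots emit the home; each `0`-run triggers
exactly one chooser call whose result must differ from the home and from
the immediately preceding location — enforced by rejection redraw (at most
100 attempts) since a chooser may legitimately propose either.  Each agent
runs on an RNG substream keyed `(seed, agent_id)`, making cohorts
bit-reproducible and order-independent.  A failing agent is aborted with a
warning; the cohort continues.

## Measures and comparison

A visit is an arrival event (one maximal stay); this one convention feeds
the visit counts behind preferential return, the radius of gyration
weights, f(L) and V.  The radius of gyration uses `p_i = n_i / Σ_k n_k`
(visit share) and the visit-weighted mean point in latitude/longitude as
the center of mass; the entropy is the standard negative Shannon form
normalised by `ln |L_u|`, defined as 0 for single-location agents so it
stays in [0, 1].

Binning is a package convention (fixed so that any two cohorts are
comparable): geometric bins with ratio 1.5 for Δr, r_g (anchor 0.1 km), Δt
(anchor 0.5 h) and V (anchor 0.5 visits); unit integer bins for N_u and D;
24 hour-of-day bins for T (pooled over agents, then normalised); 20 linear
bins on [0, 1] for S^unc; f(L) is the across-agent mean visit share at
each rank, truncated at rank 20 and renormalised.  Values beyond the last
edge are clipped into it so every distribution sums to 1.  KL divergence
uses natural logs with additive smoothing ε = 1e−12 and renormalisation;
RMSE is the per-bin root mean square difference.

## Record cleaning

CDR users: locations holding ≤ 0.5% of a user's records are dropped first,
then users left with one location, then users below 0.5 records/hour over
the dataset-wide observation span (last minus first timestamp).  The rate
uses the post-cleaning record count, consistent with the filter order.  The
pipeline is idempotent: dropping rare locations only raises the remaining
fractions.  GPS streams are split into trips at gaps longer than 20
minutes (configurable); each trip contributes its origin and destination
stop, mapped to a cell by an injected mapper (nearest centroid by
default — census-polygon lookup would need external geometry).

## The synthetic corpus

The generator plants a day-periodic routine: night hours (22–07) at home
with probability 0.9, work-day hours (09–18) at a work location with
probability 0.8, shoulder hours mixing home (0.5), work (0.2) and
excursions; excursions go to a uniformly random other location for a
heavy-tailed (Pareto, capped at 8 slots) number of slots.  Homes and work
places are drawn relevance-proportionally from a toy tessellation whose
relevances follow an exact Zipf rank–size law.  Observation is a Poisson
call process (default 0.5 calls/hour, the activity threshold of the CDR
filter).  Defaults — 100 users, 50 locations, 28 days — are the corpus
sizes used throughout the tests.  The ground truth (home, work, full
latent occupancy) is always returned next to the records.

What the generator does *not* emulate: bursty (non-Poisson) call
inter-event times, tower-geometry artifacts such as load balancing between
neighbouring cells, spatially correlated excursion targets, weekday/weekend
asymmetry, and population heterogeneity in routine strength.  Tests passing
on this corpus therefore demonstrate correctness of the estimators and
generators under a known routine-plus-noise regime, not fidelity to any
particular real population.

## Problem sizes and numerical notes

Cohort-scale checks run 100 agents × 336 hourly slots on 50-location
tessellations, and learner-recovery checks use 500 diaries of four weekly
periods — sizes at which Monte-Carlo error is well inside the asserted
tolerances while a full 3×3 generator grid still runs in seconds.  The
recovery experiment uses a day-periodic reference chain so that every state
is visited thousands of times at that corpus size; with a week-periodic
chain the rarely visited night states would be estimated from only ~10²
events each, and a uniform 0.05 max-error bound would not be a meaningful
check of correctness.  Statistical assertions use three-standard-error
bands or chi-square/KS tests at α = 0.01 with seeded generators.

## Known limitations

- One typical location per agent; no activity labels, social ties, travel
  times or road networks.
- The gravity kernel's deterrence exponent and the EPR constants are fixed
  defaults, not refitted from data by the package.
- The trips-per-hour profile of a fitted chain is obtained by Monte-Carlo
  over generated diaries; an exact stationary computation over the
  2N-state jump chain is possible but not implemented.
- Degenerate cohorts (e.g. a single stationary agent) yield point-mass
  distributions by convention where a measure is undefined (no trips).
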