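# Methods

## Problem

When an out-of-hospital cardiac arrest (OHCA) is reported, a responder
network system (RNS) alerts registered volunteers near the patient. Legacy
systems notify everyone inside a fixed radius (typically 500 m), which
over-notifies in dense cities, ignores the difference between straight-line
and walkable route distance, and leaves volunteers to race each other for
the same AED. This package treats dispatch as a constrained assignment
problem instead: pick (user, AED, emergency) triples so that each selected
volunteer carries a uniquely assigned AED and the time-to-patient is as
small as possible, across several simultaneous emergencies.

## Model

For users i = 1..n, AEDs j = 1..m and emergencies k = 1..o, the candidate
path (i, j, k) has travel time

    t_ijk = ( d(user_i, aed_j) + d(aed_j, emergency_k) ) / walking_speed_i

with d a pluggable distance: Euclidean (default), Manhattan/grid, haversine
for geographic coordinates, or a tabulated route-distance matrix (the hook
for real street networks, where d may be asymmetric). A path is feasible iff
the volunteer's phone outlives the trip,

    battery_level_i / battery_consumption_rate_i >= t_ijk

(boundary inclusive: exactly enough battery counts as feasible), and iff
t_ijk does not exceed the dispatcher horizon (below). Battery is applied as
a data filter — infeasible paths never become decision variables — in every
method, which keeps the formulations comparable.

Constraints: a user appears in at most one match, an AED in at most one
match; an emergency may receive many responders (optionally capped).

### Objective

Minimizing total travel time directly yields the empty matching, so the
objective is inverted: maximize Σ (big_time − t_ijk) x_ijk with
big_time = max(t_ijk) + 1. The +1 makes every feasible match worth at least
one unit, so matches are never dropped merely for being the slowest; the
same "max + 1" convention defines the sentinel `max_edge_weight` used to
mark dummy and infeasible cells in the bipartite matrix. At a fixed match
count this objective is equivalent to minimizing total travel time.

### The three solvers

* **bm** — the 3-index problem is flattened to users × (AED, emergency)
  columns, padded square with sentinel-valued dummy rows/columns, and solved
  with the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`).
  One solve can select two columns sharing an AED, so the assignment is
  post-filtered (sentinel pairs dropped, duplicate AEDs resolved by keeping
  the faster match), accepted rows/columns are sentineled in place, and the
  solve repeats until an iteration accepts nothing new. Each iteration
  accepts at least one match while any feasible unmatched path remains, so
  the result is maximal and the loop is bounded by min(n, m) iterations.
* **ilp** — the exact integer program above, solved with HiGHS through
  `scipy.optimize.milp` (deterministic, proven optimal).
* **ppilp** — the travel-time-sliced variant: solve the ILP restricted to
  paths with t ≤ interval, then t ≤ 2·interval, ... up to the horizon,
  filtering out paths through already-matched users/AEDs before each band
  and accumulating matches. Each band is small, so the whole sweep is much
  cheaper than one global solve; the price is that band-local choices are
  greedy across bands (see Limitations).

### Max-min fairness

Time-optimal matching is greedy across emergencies: if one incident is
nearer to everyone, it absorbs every responder and other incidents go
unattended. The fairness option maximizes the minimum per-emergency match
count, f(k) = Σ_ij x_ijk, before the time objective. It is implemented
lexicographically as a two-stage solve: maximize the auxiliary integer
MinPair subject to MinPair ≤ f(k) + carried(k) for every k, then re-solve
the time objective with per-emergency counts held at ≥ MinPair*. Inside the
banded solver, carried(k) counts matches fixed in earlier bands, so fairness
is cumulative across bands. A single weighted objective
(W·MinPair + time objective, with W exceeding any achievable time value) is
available as `fairness_mode="weighted"` but the two-stage solve is the
default because it makes the precedence exact rather than by a large
constant.

## Parameters

| parameter | unit | default | why |
|---|---|---|---|
| `horizon` | s | 1000 | dispatcher's maximum acceptable time-to-patient; a worked dispatch convention |
| `travel_time_interval` | s | 100 | band width; one tenth of the horizon (ten bands). Larger intervals suit sparse areas, smaller ones dense cities |
| `cap` | matches | none | optional per-emergency limit on responders |
| `fairness` | — | off | max-min secondary objective as above |

The horizon is applied uniformly to all three methods. Attaching it only to
the banded solver would make cross-method comparisons meaningless (the other
methods would happily select 90-minute walks), so "reachable within the
horizon" is treated as part of problem feasibility, not of any one
algorithm.

## Synthetic scenarios

No public registry couples volunteer positions, AED locations and OHCA
sites, so experiments use a seeded generator. Defaults: urban profile on a
2 km × 2 km area with ~60 % of users clustered (σ = 250 m) around emergency
hotspots, rural profile uniform on 10 km × 10 km; walking speed
U(1.0, 1.6) m/s; battery level U(20, 100) %; battery drain
U(0.002, 0.02) %/s, giving phones 1000–50000 s of power so the battery
filter trims a realistic minority of the slowest paths. A suite mirrors the
standard size grid (35 rows spanning 2–1750 users, 1–250 AEDs, 1–5
emergencies), with per-row seeds split from a base seed via
`numpy.random.SeedSequence` so extending the grid never perturbs earlier
rows. The hand-built special case (4 users each collocated with their own
AED, routes of 60 s to e1 and 70 s to e2 via a distance matrix) isolates the
greedy-matching failure: time-only matching sends all four to e1
(total 240 s), fairness splits 2/2 (total 260 s).

What the generator does *not* emulate: real street topology (only the
matrix mode can carry it), responder acceptance behaviour, moving users,
traffic or transport modes. Passing tests therefore demonstrate algorithmic
correctness and the structural claims (combinatorics, AED-limited counts,
fairness splits, cross-method agreement), not predictions about any real
deployment.

### Suite-comparison conditions

The grid experiments are run (in `surf.experiments`) with a horizon of
6000 s — the worst-case route time of the 2 km area at the slowest walking
speed, i.e. non-binding — and a 600 s interval (the same ten-band split).
This mirrors the regime the grid experiments are meant to probe, in which
responders outnumber AEDs and every functional AED is worth carrying: in
that regime the match count of every method equals the number of AEDs, which
is exactly what the reduced-scale suite reproduces (36/36 cases with
identical counts across methods). Under a tightly binding horizon
feasibility becomes sparse, the three methods settle on different maximal
matchings, and count agreement is no longer guaranteed — that regime is
exercised by the invariant tests, not by the agreement claim. Test and
acceptance runs cap the suite at 200 users / 50 AEDs / 5 emergencies per
case so the whole 36-case × 3-method sweep finishes in well under a minute.

## Numerical choices

* Distances and times are double precision seconds/metres; entity order and
  all tie-handling are lexicographic by id, and outputs are returned in
  canonical sorted order, so identical inputs give byte-identical outputs.
* `max_edge_weight` = max travel time + 1 (1.0 for an empty path set); a
  sentinel cell therefore strictly dominates every real cell.
* Band limits are `interval, 2·interval, …` with the final band clamped to
  the horizon when the interval does not divide it; band membership uses
  `t ≤ limit` (inclusive) uniformly.
* Degenerate inputs (no users, no feasible path, no emergencies) yield an
  empty `MatchSet` from every solver, never an exception.
* The exhaustive oracle (`brute_force_match`) refuses instances with more
  than 200 candidate triples; it searches over per-user choices with an
  admissible bound on the remaining objective, and applies the identical
  lexicographic (MinPair, time) key when fairness is on.

## Known limitations

* **Banded slicing is a heuristic.** Each band is solved to optimality, but
  a fast match fixed early can displace a globally better combination, so
  the banded total time is bounded below by the full ILP's and the gap is
  typically 0–5 % on dense instances (it ties the ILP exactly when the
  interval equals the horizon). Claims that the banded solver's total time
  never exceeds the other methods' can therefore only hold with equality
  against an exact ILP; the acceptance suite asserts the claim as stated
  and records the measured outcome rather than relaxing it.
* The iterated Hungarian method is total-time-optimal for single-emergency
  scenarios (where it coincides with one optimal assignment — the suite
  reproduces bm = ilp totals to the cent there) but degrades with several
  emergencies, because duplicate-AED columns force post-filtering.
* Match-count equality across methods is an empirical property of
  responder-rich, feasibility-dense instances, not a theorem: each method
  returns a maximal matching, and distinct maximal matchings can differ in
  size when feasibility is sparse.
* Walking is the only travel mode; battery drain is linear; users do not
  move between matching and arrival.
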