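"""Travel-time-sliced ILP: solve in ascending bands, pre-filtering as you go.

The full ILP's variable count is n * m * o, which grows too fast for
real-time dispatch. This solver slices the problem by travel time: with a
band width ``travel_time_interval`` (say 100 s) and a dispatcher ``horizon``
(say 1000 s) it solves the sub-problem restricted to paths with t <= 100 s,
then t <= 200 s, ... up to the horizon. Before each band, paths whose user
or AED was matched in an earlier band are filtered out — a data-filtering
step instead of extra constraints — so each solve stays small. Matches
accumulate across bands; with fairness enabled, each band maximizes the
minimum of carried + new per-emergency counts, so fairness is cumulative.

Slicing is a heuristic: each band is solved optimally, but a fast match
fixed early can displace a globally better combination, so the full ILP's
total time is a lower bound on this solver's. With a single band
(interval == horizon) the two coincide exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .ilp_matcher import build_ilp, solve_ilp
from .path_builder import DistanceProvider, PathSet, enumerate_paths
from .scenario_model import MatchSet, Scenario, SolverOptions

__all__ = ["band_schedule", "slice_paths", "match_preprocessed", "SolverOptions"]


def band_schedule(interval: float, horizon: float) -> list[float]:
    """Band upper limits: interval, 2*interval, ..., with the last clamped to horizon."""
    if not 0 < interval <= horizon:
        raise ValueError("require 0 < interval <= horizon")
    n_full = int(np.floor(horizon / interval + 1e-9))
    bands = [interval * i for i in range(1, n_full + 1)]
    if not bands or bands[-1] < horizon - 1e-9:
        bands.append(horizon)
    else:
        bands[-1] = horizon  # absorb float drift
    return bands


def slice_paths(
    path_set: PathSet,
    iteration_travel_time: float,
    matched_users: Iterable[str] = (),
    matched_aeds: Iterable[str] = (),
) -> PathSet:
    """Battery-feasible paths with t <= the band limit and both endpoints unmatched."""
    if not iteration_travel_time > 0:
        raise ValueError("iteration_travel_time must be positive")
    mask = path_set.feasible_mask(iteration_travel_time)
    matched_users = set(matched_users)
    matched_aeds = set(matched_aeds)
    if matched_users:
        u_blocked = np.array([u in matched_users for u in path_set.user_ids], dtype=bool)
        mask &= ~u_blocked[path_set.user_idx]
    if matched_aeds:
        a_blocked = np.array([a in matched_aeds for a in path_set.aed_ids], dtype=bool)
        mask &= ~a_blocked[path_set.aed_idx]
    return path_set.subset(mask)


def match_preprocessed(
    scenario: Scenario, provider: DistanceProvider, options: SolverOptions
) -> MatchSet:
    """Accumulate matches over ascending travel-time bands up to the horizon."""
    full = enumerate_paths(scenario, provider)
    emergency_ids = full.emergency_ids
    matches = MatchSet([])
    matched_users: set[str] = set()
    matched_aeds: set[str] = set()

    for limit in band_schedule(options.travel_time_interval, options.horizon):
        band = slice_paths(full, limit, matched_users, matched_aeds)
        if band.size:
            model = build_ilp(band, options, carried=matches, emergency_ids=emergency_ids)
            new = solve_ilp(model)
            if len(new):
                matches = MatchSet(matches.matches + list(new))
                matched_users.update(m.user_id for m in new)
                matched_aeds.update(m.aed_id for m in new)
        # early stop: nothing matchable remains anywhere below the horizon
        remaining = slice_paths(full, options.horizon, matched_users, matched_aeds)
        if remaining.size == 0:
            break
    return matches
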