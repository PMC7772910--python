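"""Iterative Hungarian matching of users against (AED, emergency) columns.

The three-group problem is flattened to two groups by combining every AED
with every emergency into one column, giving a users x (AEDs * emergencies)
cost matrix of travel times. The matrix is padded square with dummy rows or
columns whose cells hold the ``max_edge_weight`` sentinel; battery-infeasible
and over-horizon cells are sentineled too, and a user whose every cell is
infeasible is dropped from the matrix entirely.

One Hungarian solve can assign two columns that share an AED (the columns
only differ in emergency), so the assignment is post-filtered — sentinel
pairs removed, duplicate AEDs resolved by keeping the faster match — and the
matrix rows/columns of everything accepted are sentineled before re-solving.
The loop stops when an iteration accepts no new match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .path_builder import DistanceProvider, PathSet, enumerate_paths
from .scenario_model import Match, MatchSet, Scenario, SolverOptions

__all__ = [
    "CostMatrix",
    "build_cost_matrix",
    "hungarian_assign",
    "postprocess_assignment",
    "match_bipartite",
]


@dataclass
class CostMatrix:
    """Square padded cost matrix; dummy rows/columns carry ``None`` labels."""

    matrix: np.ndarray
    row_users: list[str | None]
    col_pairs: list[tuple[str, str] | None]  # (aed_id, emergency_id)
    sentinel: float

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def build_cost_matrix(path_set: PathSet, horizon: float | None = None) -> CostMatrix | None:
    """Users-with-a-feasible-path x (AED, emergency) matrix, padded square.

    Returns ``None`` when no feasible path exists (the empty-result signal).
    """
    sentinel = path_set.max_edge_weight
    n = len(path_set.user_ids)
    m = len(path_set.aed_ids)
    o = len(path_set.emergency_ids)
    if path_set.size == 0:
        return None
    feas = path_set.feasible_mask(horizon)
    if not feas.any():
        return None

    cost = np.full((n, m * o), sentinel)
    col_of = path_set.aed_idx.astype(np.int64) * o + path_set.em_idx
    cost[path_set.user_idx[feas], col_of[feas]] = path_set.travel_time[feas]

    keep_rows = np.flatnonzero((cost < sentinel).any(axis=1))
    cost = cost[keep_rows]
    row_users: list[str | None] = [path_set.user_ids[r] for r in keep_rows]
    col_pairs: list[tuple[str, str] | None] = [
        (path_set.aed_ids[j], path_set.emergency_ids[k])
        for j in range(m)
        for k in range(o)
    ]

    size = max(len(row_users), len(col_pairs))
    padded = np.full((size, size), sentinel)
    padded[: cost.shape[0], : cost.shape[1]] = cost
    row_users += [None] * (size - len(row_users))
    col_pairs += [None] * (size - len(col_pairs))
    return CostMatrix(padded, row_users, col_pairs, sentinel)


def hungarian_assign(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost perfect assignment on a square matrix (Hungarian method)."""
    rows, cols = linear_sum_assignment(matrix)
    return sorted(zip(rows.tolist(), cols.tolist()))


def postprocess_assignment(
    cost_matrix: CostMatrix,
    assignments: list[tuple[int, int]],
    current_matches: MatchSet,
) -> list[Match]:
    """Filter one Hungarian solve into genuinely new, conflict-free matches.

    Sentinel-cost pairs (dummies, infeasible cells) are dropped; then the
    candidates and the already-selected matches are merged under
    user-uniqueness and AED-uniqueness, keeping the lower travel time (ties
    break on lexicographic ids). Only matches not already selected are
    returned.
    """
    candidates: list[Match] = []
    for r, c in assignments:
        user = cost_matrix.row_users[r]
        pair = cost_matrix.col_pairs[c]
        t = float(cost_matrix.matrix[r, c])
        if user is None or pair is None or t >= cost_matrix.sentinel:
            continue
        candidates.append(Match(user, pair[0], pair[1], t))

    pool = list(current_matches.matches) + candidates
    pool.sort(key=lambda m: (m.travel_time, m.user_id, m.aed_id, m.emergency_id))
    used_users: set[str] = set()
    used_aeds: set[str] = set()
    kept: list[Match] = []
    for m in pool:
        if m.user_id in used_users or m.aed_id in used_aeds:
            continue
        used_users.add(m.user_id)
        used_aeds.add(m.aed_id)
        kept.append(m)
    existing = set(current_matches.matches)
    return [m for m in kept if m not in existing]


def match_bipartite(
    scenario: Scenario, provider: DistanceProvider, options: SolverOptions
) -> MatchSet:
    """Iterated Hungarian matching until no new acceptable match is found."""
    path_set = enumerate_paths(scenario, provider)
    cm = build_cost_matrix(path_set, horizon=options.horizon)
    if cm is None:
        return MatchSet([])

    matches = MatchSet([])
    user_row = {u: r for r, u in enumerate(cm.row_users) if u is not None}
    aed_cols: dict[str, list[int]] = {}
    for c, pair in enumerate(cm.col_pairs):
        if pair is not None:
            aed_cols.setdefault(pair[0], []).append(c)

    for _ in range(cm.size):
        if (cm.matrix >= cm.sentinel).all():
            break
        assignments = hungarian_assign(cm.matrix)
        new = postprocess_assignment(cm, assignments, matches)
        if not new:
            break
        matches = MatchSet(matches.matches + new)
        for m in new:
            cm.matrix[user_row[m.user_id], :] = cm.sentinel
            for c in aed_cols[m.aed_id]:
                cm.matrix[:, c] = cm.sentinel
    return matches
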