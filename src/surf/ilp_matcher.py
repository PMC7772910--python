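"""Integer-linear-programming formulation of the responder matching problem.

One binary variable x_ijk per battery-feasible candidate path (user i, AED j,
emergency k). Constraints: each user in at most one match, each AED in at
most one match, optionally at most ``cap`` matches per emergency. Minimizing
total travel time directly would return the empty matching, so the objective
is inverted: maximize sum (big_time - t_ijk) * x_ijk with

    big_time = max(t_ijk) + 1

so every feasible match is worth at least 1 and slower paths are worth less.

The optional max-min fairness secondary objective maximizes the minimum
per-emergency match count *before* the time objective (lexicographic
two-stage solve): an auxiliary integer MinPair with MinPair <= f(k) for every
emergency k is maximized first, then the time objective is maximized with the
per-emergency counts held at >= MinPair*. ``carried`` counts from earlier
travel-time bands are included in f(k) so fairness is cumulative across the
preprocessed solver's iterations.

Solved with HiGHS via :func:`scipy.optimize.milp` (exact and deterministic).
An exhaustive depth-first oracle (:func:`brute_force_match`) covers instances
with n*m*o <= 200 and is the independent check used by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .path_builder import DistanceProvider, PathSet, enumerate_paths
from .scenario_model import Match, MatchSet, Scenario, SolverOptions

__all__ = [
    "IlpModel",
    "build_ilp",
    "solve_ilp",
    "add_fairness",
    "set_emergency_cap",
    "match_ilp",
    "brute_force_match",
    "summarize",
    "objective_value",
    "lexicographic_value",
    "export_lp",
]

#: weight of MinPair in the single-objective "weighted" fairness mode; any
#: value larger than the maximum achievable time objective makes the weighted
#: mode agree with the lexicographic one on MinPair.
_FAIRNESS_WEIGHT_SLACK = 1.0

BRUTE_FORCE_GUARD = 200


@dataclass
class IlpModel:
    """A built (not yet solved) model over the feasible paths of one instance."""

    path_set: PathSet  # already restricted to the variables' paths
    big_time: float
    emergency_ids: list[str]  # all emergencies of the scenario, for fairness
    fairness: bool = False
    fairness_mode: str = "lexicographic"
    cap: int | None = None
    carried_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return self.path_set.size

    @property
    def inverted_times(self) -> np.ndarray:
        return self.big_time - self.path_set.travel_time

    @property
    def is_empty(self) -> bool:
        return self.n_variables == 0


def build_ilp(
    path_set: PathSet,
    options: SolverOptions,
    carried: MatchSet | Mapping[str, int] | None = None,
    emergency_ids: Sequence[str] | None = None,
) -> IlpModel:
    """Build the model over the battery-feasible paths within the horizon.

    The battery constraint is applied as a data filter (no variables are
    created for infeasible paths) rather than as model constraints, in both
    the plain and the preprocessed formulation. ``carried`` matches from
    earlier bands feed the cumulative fairness counts and the residual
    per-emergency caps.
    """
    feasible = path_set.subset(path_set.feasible_mask(options.horizon))
    if isinstance(carried, MatchSet):
        carried_counts = carried.per_emergency_counts
    else:
        carried_counts = dict(carried or {})
    return IlpModel(
        path_set=feasible,
        big_time=feasible.max_edge_weight,
        emergency_ids=list(emergency_ids if emergency_ids is not None else path_set.emergency_ids),
        fairness=options.fairness,
        fairness_mode=options.fairness_mode,
        cap=options.cap,
        carried_counts=carried_counts,
    )


def add_fairness(
    model: IlpModel, carried: MatchSet | Mapping[str, int] | None = None
) -> IlpModel:
    """Enable the max-min secondary objective (cumulative over ``carried``)."""
    model.fairness = True
    if carried is not None:
        model.carried_counts = (
            carried.per_emergency_counts if isinstance(carried, MatchSet) else dict(carried)
        )
    return model


def set_emergency_cap(model: IlpModel, cap: int) -> IlpModel:
    """Limit every emergency to at most ``cap`` matches (across carried + new)."""
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    model.cap = cap
    return model


def _uniqueness_constraints(ps: PathSet) -> list[LinearConstraint]:
    """User-once and AED-once rows over the variable vector."""
    nvar = ps.size
    cons = []
    for idx, count in ((ps.user_idx, len(ps.user_ids)), (ps.aed_idx, len(ps.aed_ids))):
        present = np.unique(idx)
        if present.size == 0:
            continue
        remap = -np.ones(count, dtype=np.int64)
        remap[present] = np.arange(present.size)
        a = sparse.csr_matrix(
            (np.ones(nvar), (remap[idx], np.arange(nvar))), shape=(present.size, nvar)
        )
        cons.append(LinearConstraint(a, -np.inf, 1.0))
    return cons


def _emergency_matrix(ps: PathSet) -> sparse.csr_matrix:
    """(n_emergencies, n_vars) incidence of variables on scenario emergencies."""
    nvar = ps.size
    return sparse.csr_matrix(
        (np.ones(nvar), (ps.em_idx, np.arange(nvar))),
        shape=(len(ps.emergency_ids), nvar),
    )


def _cap_constraint(model: IlpModel) -> LinearConstraint | None:
    if model.cap is None:
        return None
    ps = model.path_set
    a = _emergency_matrix(ps)
    carried = np.array(
        [model.carried_counts.get(e, 0) for e in ps.emergency_ids], dtype=float
    )
    ub = np.maximum(model.cap - carried, 0.0)
    return LinearConstraint(a, -np.inf, ub)


def _solve_stage(
    c: np.ndarray,
    constraints: list[LinearConstraint],
    integrality: np.ndarray,
    bounds: Bounds,
) -> np.ndarray:
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options={"presolve": True},
    )
    if not res.success:  # pragma: no cover - empty solution is always feasible
        raise RuntimeError(f"MILP solver failed unexpectedly: {res.message}")
    return res.x


def _decode(model: IlpModel, x: np.ndarray) -> MatchSet:
    ps = model.path_set
    chosen = np.flatnonzero(x[: ps.size] > 0.5)
    return MatchSet(
        [
            Match(
                user_id=ps.user_ids[ps.user_idx[p]],
                aed_id=ps.aed_ids[ps.aed_idx[p]],
                emergency_id=ps.emergency_ids[ps.em_idx[p]],
                travel_time=float(ps.travel_time[p]),
            )
            for p in chosen
        ]
    )


def solve_ilp(model: IlpModel) -> MatchSet:
    """Solve to proven optimality and decode the selected triples."""
    if model.is_empty:
        return MatchSet([])
    ps = model.path_set
    nvar = ps.size
    coeffs = model.inverted_times
    base_cons = _uniqueness_constraints(ps)
    cap_con = _cap_constraint(model)
    if cap_con is not None:
        base_cons = base_cons + [cap_con]

    if not model.fairness or len(model.emergency_ids) <= 1:
        x = _solve_stage(
            -coeffs,
            base_cons,
            np.ones(nvar),
            Bounds(np.zeros(nvar), np.ones(nvar)),
        )
        return _decode(model, x)

    # fairness: x variables plus the auxiliary MinPair as the last variable
    em_mat = _emergency_matrix(ps)
    carried = np.array(
        [model.carried_counts.get(e, 0) for e in ps.emergency_ids], dtype=float
    )
    nvar_f = nvar + 1
    integrality = np.ones(nvar_f)
    ub = np.concatenate([np.ones(nvar), [float(len(ps.user_ids)) + carried.max(initial=0.0)]])
    bounds = Bounds(np.zeros(nvar_f), ub)

    def widen(con: LinearConstraint) -> LinearConstraint:
        a = sparse.hstack([con.A, sparse.csr_matrix((con.A.shape[0], 1))], format="csr")
        return LinearConstraint(a, con.lb, con.ub)

    cons_f = [widen(con) for con in base_cons]
    # MinPair - sum_ij x_ijk <= carried_k for every emergency k of the scenario
    minpair_col = sparse.csr_matrix(np.ones((len(ps.emergency_ids), 1)))
    cons_f.append(
        LinearConstraint(sparse.hstack([-em_mat, minpair_col], format="csr"), -np.inf, carried)
    )

    if model.fairness_mode == "weighted":
        weight = float(coeffs.sum()) + _FAIRNESS_WEIGHT_SLACK
        c_vec = -np.concatenate([coeffs, [weight]])
        x = _solve_stage(c_vec, cons_f, integrality, bounds)
        return _decode(model, x)

    # lexicographic: maximize MinPair, then the time objective at MinPair fixed
    c_stage1 = np.zeros(nvar_f)
    c_stage1[-1] = -1.0
    x1 = _solve_stage(c_stage1, cons_f, integrality, bounds)
    min_pair = int(round(x1[-1]))

    lb_counts = np.maximum(min_pair - carried, 0.0)
    stage2_cons = base_cons + [LinearConstraint(em_mat, lb_counts, np.inf)]
    x2 = _solve_stage(
        -coeffs, stage2_cons, np.ones(nvar), Bounds(np.zeros(nvar), np.ones(nvar))
    )
    return _decode(model, x2)


def match_ilp(
    scenario: Scenario, provider: DistanceProvider, options: SolverOptions
) -> MatchSet:
    """Enumerate paths, build and solve the full ILP for one scenario."""
    path_set = enumerate_paths(scenario, provider)
    model = build_ilp(path_set, options)
    return solve_ilp(model)


# ---------------------------------------------------------------------------
# objective accounting and the exhaustive oracle


def objective_value(match_set: MatchSet, big_time: float) -> float:
    """Inverted-time objective sum (big_time - t) over the matches."""
    return float(sum(big_time - m.travel_time for m in match_set.matches))


def lexicographic_value(
    match_set: MatchSet,
    big_time: float,
    emergency_ids: Sequence[str],
    carried: Mapping[str, int] | None = None,
) -> tuple[int, float]:
    """(MinPair, time objective) — the fairness solve maximizes this pair."""
    carried = carried or {}
    counts = match_set.per_emergency_counts
    min_pair = min(
        (counts.get(e, 0) + carried.get(e, 0) for e in emergency_ids), default=0
    )
    return (int(min_pair), objective_value(match_set, big_time))


def brute_force_match(
    path_set: PathSet,
    options: SolverOptions,
    carried: MatchSet | Mapping[str, int] | None = None,
    emergency_ids: Sequence[str] | None = None,
) -> MatchSet:
    """Exhaustive oracle: the optimal matching by depth-first search.

    Explores every user-disjoint, AED-disjoint subset of the feasible paths
    (with admissible-bound pruning) and returns the one maximizing the same
    objective as the ILP — lexicographic (MinPair, time) when fairness is on.
    Ties break on the lexicographically smallest match list. Guarded to
    instances with at most ``BRUTE_FORCE_GUARD`` candidate triples.
    """
    if path_set.size > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force refused: {path_set.size} candidate paths exceed the "
            f"guard of {BRUTE_FORCE_GUARD}"
        )
    if isinstance(carried, MatchSet):
        carried = carried.per_emergency_counts
    carried = dict(carried or {})
    em_ids = list(emergency_ids if emergency_ids is not None else path_set.emergency_ids)

    feasible = path_set.subset(path_set.feasible_mask(options.horizon))
    big = feasible.max_edge_weight
    fairness = options.fairness and len(em_ids) > 1
    cap = options.cap

    # candidate pairs per user, in canonical (user, aed, emergency) order
    by_user: dict[int, list[tuple[float, int, int, float]]] = {}
    for p in range(feasible.size):
        by_user.setdefault(int(feasible.user_idx[p]), []).append(
            (
                big - float(feasible.travel_time[p]),
                int(feasible.aed_idx[p]),
                int(feasible.em_idx[p]),
                float(feasible.travel_time[p]),
            )
        )
    users = sorted(by_user)
    max_coeff = [max(c for c, *_ in by_user[u]) for u in users]
    # best possible additional time-objective from user position i onward
    suffix = np.zeros(len(users) + 1)
    for i in range(len(users) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + max_coeff[i]

    em_index = {e: i for i, e in enumerate(feasible.emergency_ids)}
    carried_vec = [carried.get(e, 0) for e in feasible.emergency_ids]
    # emergencies in the scenario but absent from the path set still bound MinPair
    extra_floor = min(
        (carried.get(e, 0) for e in em_ids if e not in em_index),
        default=math.inf,
    )

    best_key: tuple | None = None
    best_sel: list[tuple[int, int, int, float]] | None = None

    counts = list(carried_vec)
    used_aeds: set[int] = set()
    selection: list[tuple[int, int, int, float]] = []

    def key_of(time_obj: float) -> tuple:
        if fairness:
            mp = min(min(counts, default=0), extra_floor)
            return (mp if mp != math.inf else 0, time_obj)
        return (time_obj,)

    def canonical(sel) -> tuple:
        return tuple(sorted((u, a, e) for u, a, e, _ in sel))

    def consider(time_obj: float) -> None:
        nonlocal best_key, best_sel
        key = key_of(time_obj)
        if best_key is None or key > best_key or (
            key == best_key and canonical(selection) < canonical(best_sel)
        ):
            best_key = key
            best_sel = list(selection)

    def upper_bound(i: int, time_obj: float) -> tuple:
        remaining = len(users) - i
        if fairness:
            mp_ub = min(min(counts, default=0) + remaining, extra_floor)
            return (mp_ub if mp_ub != math.inf else 0, time_obj + suffix[i])
        return (time_obj + suffix[i],)

    def dfs(i: int, time_obj: float) -> None:
        consider(time_obj)
        if i == len(users):
            return
        if best_key is not None and upper_bound(i, time_obj) < best_key:
            return
        u = users[i]
        for coeff, a, e, t in by_user[u]:
            if a in used_aeds:
                continue
            if cap is not None and counts[e] >= cap:
                continue
            used_aeds.add(a)
            counts[e] += 1
            selection.append((u, a, e, t))
            dfs(i + 1, time_obj + coeff)
            selection.pop()
            counts[e] -= 1
            used_aeds.remove(a)
        dfs(i + 1, time_obj)  # user u unmatched

    dfs(0, 0.0)
    assert best_sel is not None
    return MatchSet(
        [
            Match(
                user_id=feasible.user_ids[u],
                aed_id=feasible.aed_ids[a],
                emergency_id=feasible.emergency_ids[e],
                travel_time=t,
            )
            for u, a, e, t in best_sel
        ]
    )


def summarize(match_set: MatchSet) -> dict:
    """Totals reported for every solution."""
    return {
        "n_matches": len(match_set),
        "total_match_time": match_set.total_match_time,
        "per_emergency_counts": match_set.per_emergency_counts,
        "unique_emergencies_covered": match_set.unique_emergencies_covered,
    }


def export_lp(model: IlpModel, path: str | Path) -> None:
    """Write the model as LP-format text for audit (objective in maximize form)."""
    ps = model.path_set
    names = [
        f"x_{ps.user_ids[ps.user_idx[p]]}_{ps.aed_ids[ps.aed_idx[p]]}"
        f"_{ps.emergency_ids[ps.em_idx[p]]}"
        for p in range(ps.size)
    ]
    coeffs = model.inverted_times
    lines = ["Maximize", " obj: " + " + ".join(f"{coeffs[p]:.6g} {names[p]}" for p in range(ps.size))]
    lines.append("Subject To")
    n_con = 0
    for label, idx, ids in (
        ("user", ps.user_idx, ps.user_ids),
        ("aed", ps.aed_idx, ps.aed_ids),
    ):
        for entity in np.unique(idx):
            members = [names[p] for p in np.flatnonzero(idx == entity)]
            n_con += 1
            lines.append(f" {label}_{ids[entity]}: " + " + ".join(members) + " <= 1")
    if model.cap is not None:
        for e in np.unique(ps.em_idx):
            members = [names[p] for p in np.flatnonzero(ps.em_idx == e)]
            rhs = model.cap - model.carried_counts.get(ps.emergency_ids[e], 0)
            lines.append(f" cap_{ps.emergency_ids[e]}: " + " + ".join(members) + f" <= {rhs}")
    lines.append("Binary")
    lines.append(" " + " ".join(names))
    lines.append("End")
    Path(path).write_text("\n".join(lines) + "\n")
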