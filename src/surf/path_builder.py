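"""Travel-time model, battery feasibility and candidate-path enumeration.

A candidate path is one (user, AED, emergency) triple: the user walks to the
AED, picks it up, and continues to the patient. Its travel time is

    t = (d(user, AED) + d(AED, emergency)) / walking_speed

with d given by a pluggable distance provider. Straight-line distance is the
default; a tabulated route-distance matrix is the hook for real street
networks, where the walkable route can be several times longer than the
straight line (the reason radius-based responder selection over-notifies).

The sentinel ``max_edge_weight`` is one second more than the slowest
enumerated path, so a sentinel-valued matrix cell can never be confused with
a real path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .scenario_model import AED, Emergency, Scenario, User

__all__ = [
    "DistanceProvider",
    "CandidatePath",
    "PathSet",
    "provider_for",
    "travel_time",
    "powered_time",
    "battery_feasible",
    "enumerate_paths",
    "radius_select",
]

_EARTH_RADIUS_M = 6_371_000.0


class DistanceConfigurationError(RuntimeError):
    """A required distance (e.g. a matrix entry) is not defined."""


def _haversine_m(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance in metres between lon/lat degree arrays (broadcast)."""
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class DistanceProvider:
    """Pairwise travel distances in metres.

    Modes:

    * ``euclidean`` — straight-line distance (haversine when the scenario is
      geographic).
    * ``manhattan_grid`` — L1 distance, optionally after snapping coordinates
      to a street grid of ``grid_spacing`` metres; a cheap stand-in for a
      rectilinear street network.
    * ``matrix`` — tabulated route distances from the scenario's
      ``distance_matrix``; the only mode in which d(a, b) may differ from
      d(b, a).
    """

    mode: str = "euclidean"
    grid_spacing: float | None = None
    matrix: dict[str, dict[str, float]] | None = None
    coordinate_system: str = "planar_m"

    def __post_init__(self) -> None:
        if self.mode not in ("euclidean", "manhattan_grid", "matrix"):
            raise ValueError(f"unknown distance mode {self.mode!r}")
        if self.mode == "matrix" and self.matrix is None:
            raise DistanceConfigurationError("matrix mode requires a distance_matrix")

    def _snap(self, xy: np.ndarray) -> np.ndarray:
        if self.grid_spacing:
            return np.round(xy / self.grid_spacing) * self.grid_spacing
        return xy

    def pairwise(
        self,
        from_ids: Sequence[str],
        from_pos: np.ndarray,
        to_ids: Sequence[str],
        to_pos: np.ndarray,
    ) -> np.ndarray:
        """(len(from), len(to)) distance array in metres."""
        if len(from_ids) == 0 or len(to_ids) == 0:
            return np.zeros((len(from_ids), len(to_ids)))
        if self.mode == "matrix":
            assert self.matrix is not None
            out = np.empty((len(from_ids), len(to_ids)))
            for i, src in enumerate(from_ids):
                row = self.matrix.get(src)
                for j, dst in enumerate(to_ids):
                    if row is None or dst not in row:
                        raise DistanceConfigurationError(
                            f"distance_matrix has no entry {src!r} -> {dst!r}"
                        )
                    out[i, j] = row[dst]
            return out
        a = np.asarray(from_pos, dtype=float)[:, None, :]
        b = np.asarray(to_pos, dtype=float)[None, :, :]
        if self.coordinate_system == "geographic":
            aa, bb = np.broadcast_arrays(a, b)
            if self.mode == "manhattan_grid":
                # L1 on the sphere: a meridian leg then a parallel leg via the corner
                corner = np.stack([aa[..., 0], bb[..., 1]], axis=-1)
                return _haversine_m(aa, corner) + _haversine_m(corner, bb)
            return _haversine_m(aa, bb)
        if self.mode == "manhattan_grid":
            a, b = self._snap(a), self._snap(b)
            return np.abs(a - b).sum(axis=-1)
        return np.sqrt(((a - b) ** 2).sum(axis=-1))

    def distance(self, from_id: str, from_pos, to_id: str, to_pos) -> float:
        return float(
            self.pairwise(
                [from_id], np.asarray([from_pos], dtype=float),
                [to_id], np.asarray([to_pos], dtype=float),
            )[0, 0]
        )


def provider_for(scenario: Scenario, mode: str | None = None, **kwargs) -> DistanceProvider:
    """Default provider for a scenario: matrix if it carries one, else euclidean."""
    if mode is None:
        mode = "matrix" if scenario.distance_matrix is not None else "euclidean"
    return DistanceProvider(
        mode=mode,
        matrix=scenario.distance_matrix,
        coordinate_system=scenario.coordinate_system,
        **kwargs,
    )


@dataclass(frozen=True)
class CandidatePath:
    """One (user, AED, emergency) triple with route length and travel time."""

    user_id: str
    aed_id: str
    emergency_id: str
    travel_distance: float  # metres, user -> AED -> emergency
    travel_time: float  # seconds
    battery_feasible: bool


class PathSet:
    """All candidate paths of a scenario, stored column-wise for scale.

    ``user_ids`` are the available users and ``aed_ids`` the functional AEDs,
    each lexicographically sorted; the flat arrays hold one entry per
    (user, AED, emergency) triple in row-major (user, AED, emergency) order.
    For a full enumeration the number of paths is exactly
    ``len(user_ids) * len(aed_ids) * len(emergency_ids)``; subsets keep the
    id axes and drop rows.
    """

    def __init__(
        self,
        user_ids: Sequence[str],
        aed_ids: Sequence[str],
        emergency_ids: Sequence[str],
        user_idx: np.ndarray,
        aed_idx: np.ndarray,
        em_idx: np.ndarray,
        travel_distance: np.ndarray,
        travel_time: np.ndarray,
        battery_ok: np.ndarray,
    ) -> None:
        self.user_ids = list(user_ids)
        self.aed_ids = list(aed_ids)
        self.emergency_ids = list(emergency_ids)
        self.user_idx = np.asarray(user_idx, dtype=np.int32)
        self.aed_idx = np.asarray(aed_idx, dtype=np.int32)
        self.em_idx = np.asarray(em_idx, dtype=np.int32)
        self.travel_distance = np.asarray(travel_distance, dtype=float)
        self.travel_time = np.asarray(travel_time, dtype=float)
        self.battery_ok = np.asarray(battery_ok, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.travel_time.size)

    @property
    def max_edge_weight(self) -> float:
        """Sentinel cost: one more than the slowest path (1.0 for an empty set)."""
        return float(self.travel_time.max()) + 1.0 if self.size else 1.0

    @property
    def paths(self) -> list[CandidatePath]:
        return [
            CandidatePath(
                user_id=self.user_ids[self.user_idx[p]],
                aed_id=self.aed_ids[self.aed_idx[p]],
                emergency_id=self.emergency_ids[self.em_idx[p]],
                travel_distance=float(self.travel_distance[p]),
                travel_time=float(self.travel_time[p]),
                battery_feasible=bool(self.battery_ok[p]),
            )
            for p in range(self.size)
        ]

    def feasible_mask(self, horizon: float | None = None) -> np.ndarray:
        """Battery-feasible paths, optionally also within the dispatcher horizon."""
        mask = self.battery_ok.copy()
        if horizon is not None:
            mask &= self.travel_time <= horizon
        return mask

    def subset(self, mask: np.ndarray) -> "PathSet":
        mask = np.asarray(mask, dtype=bool)
        return PathSet(
            self.user_ids,
            self.aed_ids,
            self.emergency_ids,
            self.user_idx[mask],
            self.aed_idx[mask],
            self.em_idx[mask],
            self.travel_distance[mask],
            self.travel_time[mask],
            self.battery_ok[mask],
        )


def travel_time(
    user: User, aed: AED, emergency: Emergency, provider: DistanceProvider
) -> float:
    """Seconds for ``user`` to reach ``emergency`` while collecting ``aed`` en route."""
    if not user.walking_speed > 0:
        raise ValueError(f"user {user.id!r}: walking_speed must be positive")
    d = provider.distance(user.id, user.position, aed.id, aed.position) + provider.distance(
        aed.id, aed.position, emergency.id, emergency.position
    )
    return d / user.walking_speed


def powered_time(user: User) -> float:
    """Seconds the user's phone stays powered at the current consumption rate."""
    if not user.battery_consumption_rate > 0:
        raise ValueError(f"user {user.id!r}: battery_consumption_rate must be positive")
    return user.battery_level / user.battery_consumption_rate


def battery_feasible(user: User, travel_time_s: float) -> bool:
    """True iff the phone stays powered for the whole trip (boundary counts as feasible)."""
    return powered_time(user) >= travel_time_s


def enumerate_paths(scenario: Scenario, provider: DistanceProvider) -> PathSet:
    """One candidate path per (available user, functional AED, emergency) triple.

    Unavailable users and non-functional AEDs are excluded here — not at load
    time — so scenarios stay auditable. Entity order is lexicographic by id.
    """
    users = sorted((u for u in scenario.users if u.available), key=lambda u: u.id)
    aeds = sorted((a for a in scenario.aeds if a.functional), key=lambda a: a.id)
    emergencies = sorted(scenario.emergencies, key=lambda e: e.id)
    n, m, o = len(users), len(aeds), len(emergencies)
    user_ids = [u.id for u in users]
    aed_ids = [a.id for a in aeds]
    em_ids = [e.id for e in emergencies]
    if n * m * o == 0:
        z = np.zeros(0)
        return PathSet(user_ids, aed_ids, em_ids, z, z, z, z, z, z.astype(bool))

    u_pos = np.asarray([u.position for u in users], dtype=float)
    a_pos = np.asarray([a.position for a in aeds], dtype=float)
    e_pos = np.asarray([e.position for e in emergencies], dtype=float)
    d_ua = provider.pairwise(user_ids, u_pos, aed_ids, a_pos)  # (n, m)
    d_ae = provider.pairwise(aed_ids, a_pos, em_ids, e_pos)  # (m, o)

    dist = d_ua[:, :, None] + d_ae[None, :, :]  # (n, m, o)
    speeds = np.asarray([u.walking_speed for u in users], dtype=float)
    time = dist / speeds[:, None, None]
    powered = np.asarray([powered_time(u) for u in users], dtype=float)
    ok = time <= powered[:, None, None]

    ui, ai, ei = np.meshgrid(np.arange(n), np.arange(m), np.arange(o), indexing="ij")
    return PathSet(
        user_ids,
        aed_ids,
        em_ids,
        ui.ravel(),
        ai.ravel(),
        ei.ravel(),
        dist.ravel(),
        time.ravel(),
        ok.ravel(),
    )


def radius_select(
    users: Iterable[User],
    emergency: Emergency,
    radius: float,
    coordinate_system: str = "planar_m",
) -> list[User]:
    """The legacy radius-notification baseline: users within straight-line ``radius``.

    Provided for comparison output only — it ignores route distance, walking
    speed and battery, which is precisely the flaw time-based matching fixes.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    provider = DistanceProvider(mode="euclidean", coordinate_system=coordinate_system)
    selected = []
    for u in sorted(users, key=lambda u: u.id):
        d = provider.distance(u.id, u.position, emergency.id, emergency.position)
        if d <= radius:
            selected.append(u)
    return selected
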