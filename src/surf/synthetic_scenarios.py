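"""Seeded synthetic scenarios: the experiment size grid and the fairness special case.

No public registry of responder positions, AED locations and cardiac-arrest
sites exists, so experiments run on generated scenarios. The generator
emulates two settings: a compact *urban* area (2 km x 2 km) where responders
cluster around the emergency hotspots, and a sparse *rural* area
(10 km x 10 km) with uniform placement. Walking speeds, battery levels and
battery drain rates are drawn uniformly from ranges typical of pedestrians
and smartphones; everything is a pure function of the seed.

The standard experiment grid spans 2-1750 users, 1-250 AEDs and 1-5
simultaneous emergencies (35 size rows), plus a small hand-built special
case — four users, each standing next to their own AED, all slightly nearer
emergency e1 than e2 — on which time-only matching sends all four responders
to e1 and leaves e2 unattended, while max-min fairness splits them 2/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenario_model import AED, Emergency, Scenario, User

__all__ = [
    "GeneratorSpec",
    "generate_scenario",
    "special_case_scenario",
    "generate_suite",
    "TABLE_ROWS",
    "suite_rows",
]

#: the experiment size grid: (n_users, n_aeds, n_emergencies) per test case;
#: the 36th case is the hand-built special scenario.
TABLE_ROWS: list[tuple[int, int, int]] = [
    (50, 2, 1), (100, 3, 1), (150, 4, 1), (200, 5, 1), (250, 6, 1),
    (300, 7, 1), (350, 8, 1), (400, 9, 1), (450, 10, 1), (500, 10, 1),
    (550, 10, 1), (600, 20, 1), (650, 30, 1), (700, 40, 1), (750, 50, 1),
    (800, 60, 2), (850, 70, 2), (900, 80, 2), (950, 90, 2), (1000, 100, 2),
    (1050, 110, 3), (1100, 120, 3), (1150, 130, 3), (1200, 140, 3), (1250, 150, 3),
    (1300, 160, 4), (1350, 170, 4), (1400, 180, 4), (1450, 190, 4), (1500, 200, 4),
    (1550, 210, 5), (1600, 220, 5), (1650, 230, 5), (1700, 240, 5), (1750, 250, 5),
]

_PROFILE_AREA = {"urban": 2000.0, "rural": 10000.0}


@dataclass
class GeneratorSpec:
    """Everything that determines one generated scenario.

    Ranges are (low, high) for uniform draws. Battery units are percent
    points and percent/second; the defaults give phones 1000-50000 s of
    power, so the battery filter removes a realistic minority of the slowest
    paths rather than gutting the instance.
    """

    n_users: int
    n_aeds: int
    n_emergencies: int
    density_profile: str = "urban"
    area_side: float | None = None  # metres; default from profile
    walking_speed_range: tuple[float, float] = (1.0, 1.6)
    battery_level_range: tuple[float, float] = (20.0, 100.0)
    battery_rate_range: tuple[float, float] = (0.002, 0.02)
    distance_mode: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_users, self.n_aeds, self.n_emergencies) < 0:
            raise ValueError("entity counts must be non-negative")
        if self.density_profile not in _PROFILE_AREA:
            raise ValueError(f"unknown density_profile {self.density_profile!r}")
        if self.area_side is None:
            self.area_side = _PROFILE_AREA[self.density_profile]


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(max(n, 1))))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_scenario(spec: GeneratorSpec) -> Scenario:
    """Draw one scenario; identical spec (including seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    side = float(spec.area_side)

    em_pos = rng.uniform(0.0, side, size=(spec.n_emergencies, 2))
    aed_pos = rng.uniform(0.0, side, size=(spec.n_aeds, 2))

    if spec.density_profile == "urban" and spec.n_emergencies > 0 and spec.n_users > 0:
        # ~60% of responders cluster around emergency hotspots, rest uniform
        n_clustered = int(round(0.6 * spec.n_users))
        hotspot = rng.integers(0, spec.n_emergencies, size=n_clustered)
        clustered = em_pos[hotspot] + rng.normal(0.0, side / 8.0, size=(n_clustered, 2))
        clustered = np.clip(clustered, 0.0, side)
        uniform = rng.uniform(0.0, side, size=(spec.n_users - n_clustered, 2))
        user_pos = np.vstack([clustered, uniform])
    else:
        user_pos = rng.uniform(0.0, side, size=(spec.n_users, 2))

    speeds = rng.uniform(*spec.walking_speed_range, size=spec.n_users)
    levels = rng.uniform(*spec.battery_level_range, size=spec.n_users)
    rates = rng.uniform(*spec.battery_rate_range, size=spec.n_users)

    users = [
        User(
            id=uid,
            position=(float(user_pos[i, 0]), float(user_pos[i, 1])),
            walking_speed=float(speeds[i]),
            battery_level=float(levels[i]),
            battery_consumption_rate=float(rates[i]),
        )
        for i, uid in enumerate(_ids("u", spec.n_users))
    ]
    aeds = [
        AED(id=aid, position=(float(aed_pos[j, 0]), float(aed_pos[j, 1])))
        for j, aid in enumerate(_ids("a", spec.n_aeds))
    ]
    emergencies = [
        Emergency(id=eid, position=(float(em_pos[k, 0]), float(em_pos[k, 1])))
        for k, eid in enumerate(_ids("e", spec.n_emergencies))
    ]
    return Scenario(users=users, aeds=aeds, emergencies=emergencies)


def special_case_scenario() -> Scenario:
    """The greedy-matching showcase: 4 users, 4 AEDs, 2 emergencies.

    Each user stands at their own AED; via a route-distance matrix every AED
    is 72 m from e1 and 84 m from e2, and every user is 30 m from every AED
    but their own. At 1.2 m/s the own-AED routes take 60 s (e1) and 70 s
    (e2); all 32 candidate paths are battery-feasible. Time-only matching
    therefore sends all four users to e1 (total 240 s, e2 unattended);
    max-min fairness splits them 2/2 (total 260 s).
    """
    user_xy = [(0.0, 0.0), (100.0, 0.0), (200.0, 0.0), (300.0, 0.0)]
    e1 = Emergency("e1", (150.0, 50.0))
    e2 = Emergency("e2", (150.0, -60.0))
    users = [
        User(
            id=f"u{i + 1}",
            position=user_xy[i],
            walking_speed=1.2,
            battery_level=100.0,
            battery_consumption_rate=0.01,
        )
        for i in range(4)
    ]
    aeds = [AED(id=f"a{i + 1}", position=user_xy[i]) for i in range(4)]
    dm: dict[str, dict[str, float]] = {}
    for i, u in enumerate(users):
        dm[u.id] = {a.id: (0.0 if i == j else 30.0) for j, a in enumerate(aeds)}
    for a in aeds:
        dm[a.id] = {"e1": 72.0, "e2": 84.0}
    return Scenario(
        users=users, aeds=aeds, emergencies=[e1, e2], distance_matrix=dm
    )


def _row_seed(base_seed: int, index: int) -> int:
    """Splittable per-row seed: adding rows never perturbs earlier scenarios."""
    ss = np.random.SeedSequence((int(base_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def suite_rows(
    max_users: int | None = None,
    max_aeds: int | None = None,
    max_emergencies: int | None = None,
) -> list[tuple[int, int, int]]:
    """The standard grid, optionally capped per dimension for faster runs."""
    return [
        (
            min(n, max_users) if max_users else n,
            min(m, max_aeds) if max_aeds else m,
            min(o, max_emergencies) if max_emergencies else o,
        )
        for n, m, o in TABLE_ROWS
    ]


def generate_suite(
    rows: list[tuple[int, int, int]] | None = None,
    base_seed: int = 0,
    density_profile: str = "urban",
    include_special_case: bool = True,
) -> list[Scenario]:
    """One scenario per size row plus (by default) the special case as the last entry."""
    if rows is None:
        rows = TABLE_ROWS
    scenarios = [
        generate_scenario(
            GeneratorSpec(
                n_users=n,
                n_aeds=m,
                n_emergencies=o,
                density_profile=density_profile,
                seed=_row_seed(base_seed, i),
            )
        )
        for i, (n, m, o) in enumerate(rows)
    ]
    if include_special_case:
        scenarios.append(special_case_scenario())
    return scenarios
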