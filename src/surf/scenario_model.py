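"""Domain types for responder-network matching scenarios and solutions.

A scenario describes a snapshot of the world at the moment one or more
out-of-hospital cardiac arrests are reported: registered volunteer responders
(*users*) with their positions, walking speeds and phone battery state,
registered AEDs, and the emergency locations. A solution is a set of
(user, AED, emergency) triples in which every user and every AED appears at
most once, annotated with the travel time of each triple.

Scenarios round-trip through JSON (primary), CSV (one table per entity kind)
and GeoJSON (a FeatureCollection of Points).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "User",
    "AED",
    "Emergency",
    "Scenario",
    "Match",
    "MatchSet",
    "SolverOptions",
    "ScenarioFormatError",
    "ScenarioValidationError",
    "load_scenario",
    "save_scenario",
    "validate_scenario",
    "save_matches",
    "load_matches",
    "matchset_diagnostics",
]

SCHEMA_VERSION = "1"

Position = tuple[float, float]


class ScenarioFormatError(ValueError):
    """Raised when a scenario file cannot be parsed in the declared dialect."""


class ScenarioValidationError(ValueError):
    """Raised when a parsed scenario violates a hard invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class User:
    """A volunteer responder candidate.

    ``battery_level`` and ``battery_consumption_rate`` only matter through
    their ratio (seconds the phone stays powered); percent points and
    percent/second are the conventional pair and must be uniform per scenario.
    """

    id: str
    position: Position
    walking_speed: float  # m/s
    battery_level: float  # percent points
    battery_consumption_rate: float  # percent points per second
    available: bool = True


@dataclass(frozen=True)
class AED:
    """A registered automated external defibrillator; single-use per solution."""

    id: str
    position: Position
    functional: bool = True


@dataclass(frozen=True)
class Emergency:
    """A reported cardiac-arrest location; may receive several responders."""

    id: str
    position: Position


@dataclass
class Scenario:
    """Users, AEDs and emergencies, plus an optional route-distance matrix.

    ``coordinate_system`` is ``"planar_m"`` (x/y metres) or ``"geographic"``
    (lon/lat degrees, distances via haversine). ``distance_matrix`` maps
    ``from_id -> to_id -> metres`` and, when present, must cover every
    user->AED and AED->emergency pair; it is the hook for real route networks
    and may be asymmetric.
    """

    users: list[User] = field(default_factory=list)
    aeds: list[AED] = field(default_factory=list)
    emergencies: list[Emergency] = field(default_factory=list)
    coordinate_system: str = "planar_m"
    distance_matrix: dict[str, dict[str, float]] | None = None

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_aeds(self) -> int:
        return len(self.aeds)

    @property
    def n_emergencies(self) -> int:
        return len(self.emergencies)

    def user(self, user_id: str) -> User:
        return next(u for u in self.users if u.id == user_id)

    def sorted_copy(self) -> "Scenario":
        """Entities ordered lexicographically by id (the canonical ordering)."""
        return replace(
            self,
            users=sorted(self.users, key=lambda u: u.id),
            aeds=sorted(self.aeds, key=lambda a: a.id),
            emergencies=sorted(self.emergencies, key=lambda e: e.id),
        )


@dataclass(frozen=True, order=True)
class Match:
    """One selected (user, AED, emergency) triple with its travel time in seconds."""

    user_id: str
    aed_id: str
    emergency_id: str
    travel_time: float


@dataclass
class MatchSet:
    """A solution: user-disjoint, AED-disjoint matches, stored in canonical order."""

    matches: list[Match] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matches = sorted(self.matches)

    @property
    def total_match_time(self) -> float:
        """Sum of travel times over all selected matches, in seconds."""
        return float(sum(m.travel_time for m in self.matches))

    @property
    def per_emergency_counts(self) -> dict[str, int]:
        return dict(Counter(m.emergency_id for m in self.matches))

    @property
    def unique_emergencies_covered(self) -> int:
        return len({m.emergency_id for m in self.matches})

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)

    def __eq__(self, other) -> bool:
        return isinstance(other, MatchSet) and self.matches == other.matches


@dataclass
class SolverOptions:
    """Options shared by all matching methods.

    ``horizon`` is the dispatcher's maximum acceptable time-to-patient in
    seconds; paths slower than it are never matched by any method.
    ``travel_time_interval`` is the band width used by the preprocessed ILP.
    ``fairness`` switches on the max-min secondary objective (maximize the
    minimum per-emergency match count before minimizing time);
    ``fairness_mode`` selects the lexicographic two-stage solve (default) or a
    single weighted objective. ``cap`` bounds matches per emergency.
    """

    method: str = "ppilp"  # bm | ilp | ppilp
    travel_time_interval: float = 100.0
    horizon: float = 1000.0
    fairness: bool = False
    fairness_mode: str = "lexicographic"  # lexicographic | weighted
    cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("bm", "ilp", "ppilp"):
            raise ValueError(f"unknown method {self.method!r}")
        if not math.isfinite(self.horizon):
            raise ValueError("horizon must be finite")
        if not 0 < self.travel_time_interval <= self.horizon:
            raise ValueError("require 0 < travel_time_interval <= horizon")
        if self.cap is not None and self.cap < 1:
            raise ValueError("cap must be a positive integer")
        if self.fairness_mode not in ("lexicographic", "weighted"):
            raise ValueError(f"unknown fairness_mode {self.fairness_mode!r}")


# ---------------------------------------------------------------------------
# validation


def validate_scenario(scenario: Scenario) -> list[str]:
    """Return one human-readable diagnostic per violated invariant (empty if valid)."""
    diags: list[str] = []
    for kind, items in (
        ("user", scenario.users),
        ("AED", scenario.aeds),
        ("emergency", scenario.emergencies),
    ):
        counts = Counter(x.id for x in items)
        for dup, c in sorted(counts.items()):
            if c > 1:
                diags.append(f"duplicate {kind} id {dup!r} ({c} occurrences)")
    for u in scenario.users:
        if not u.walking_speed > 0:
            diags.append(f"user {u.id!r}: walking_speed must be > 0, got {u.walking_speed}")
        if not 0 <= u.battery_level <= 100:
            diags.append(f"user {u.id!r}: battery_level must be in [0, 100], got {u.battery_level}")
        if not u.battery_consumption_rate > 0:
            diags.append(
                f"user {u.id!r}: battery_consumption_rate must be > 0, "
                f"got {u.battery_consumption_rate}"
            )
    if scenario.coordinate_system not in ("planar_m", "geographic"):
        diags.append(f"unknown coordinate_system {scenario.coordinate_system!r}")
    if scenario.distance_matrix is not None:
        dm = scenario.distance_matrix
        for u in scenario.users:
            for a in scenario.aeds:
                if dm.get(u.id, {}).get(a.id) is None:
                    diags.append(f"distance_matrix missing entry {u.id!r} -> {a.id!r}")
        for a in scenario.aeds:
            for e in scenario.emergencies:
                if dm.get(a.id, {}).get(e.id) is None:
                    diags.append(f"distance_matrix missing entry {a.id!r} -> {e.id!r}")
        for src, row in dm.items():
            for dst, d in row.items():
                if d < 0:
                    diags.append(f"distance_matrix entry {src!r} -> {dst!r} is negative ({d})")
    return diags


def matchset_diagnostics(match_set: MatchSet) -> list[str]:
    """Diagnostics for the solution invariants (disjoint users, disjoint AEDs)."""
    diags: list[str] = []
    for label, key in (("user", lambda m: m.user_id), ("AED", lambda m: m.aed_id)):
        for dup, c in sorted(Counter(key(m) for m in match_set.matches).items()):
            if c > 1:
                diags.append(f"{label} {dup!r} matched {c} times")
    for m in match_set.matches:
        if not (math.isfinite(m.travel_time) and m.travel_time >= 0):
            diags.append(f"match {m} has invalid travel_time")
    return diags


# ---------------------------------------------------------------------------
# JSON


def _user_to_dict(u: User) -> dict:
    return {
        "id": u.id,
        "position": list(u.position),
        "walking_speed": u.walking_speed,
        "battery_level": u.battery_level,
        "battery_consumption_rate": u.battery_consumption_rate,
        "available": u.available,
    }


def _scenario_to_dict(s: Scenario) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "coordinate_system": s.coordinate_system,
        "users": [_user_to_dict(u) for u in s.users],
        "aeds": [
            {"id": a.id, "position": list(a.position), "functional": a.functional}
            for a in s.aeds
        ],
        "emergencies": [{"id": e.id, "position": list(e.position)} for e in s.emergencies],
    }
    if s.distance_matrix is not None:
        d["distance_matrix"] = s.distance_matrix
    return d


def _require(record: Mapping, key: str, where: str):
    try:
        return record[key]
    except KeyError:
        raise ScenarioFormatError(f"missing field {key!r} in {where}: {dict(record)!r}") from None


def _scenario_from_dict(d: Mapping) -> Scenario:
    try:
        users = [
            User(
                id=str(_require(r, "id", "user record")),
                position=(float(r["position"][0]), float(r["position"][1])),
                walking_speed=float(_require(r, "walking_speed", "user record")),
                battery_level=float(_require(r, "battery_level", "user record")),
                battery_consumption_rate=float(
                    _require(r, "battery_consumption_rate", "user record")
                ),
                available=bool(r.get("available", True)),
            )
            for r in d.get("users", [])
        ]
        aeds = [
            AED(
                id=str(_require(r, "id", "AED record")),
                position=(float(r["position"][0]), float(r["position"][1])),
                functional=bool(r.get("functional", True)),
            )
            for r in d.get("aeds", [])
        ]
        emergencies = [
            Emergency(
                id=str(_require(r, "id", "emergency record")),
                position=(float(r["position"][0]), float(r["position"][1])),
            )
            for r in d.get("emergencies", [])
        ]
    except (TypeError, IndexError, ValueError) as exc:
        if isinstance(exc, ScenarioFormatError):
            raise
        raise ScenarioFormatError(f"malformed scenario record: {exc}") from exc
    dm = d.get("distance_matrix")
    if dm is not None:
        dm = {str(src): {str(dst): float(v) for dst, v in row.items()} for src, row in dm.items()}
    scenario = Scenario(
        users=users,
        aeds=aeds,
        emergencies=emergencies,
        coordinate_system=str(d.get("coordinate_system", "planar_m")),
        distance_matrix=dm,
    )
    _raise_on_hard_errors(scenario)
    return scenario


def _raise_on_hard_errors(scenario: Scenario) -> None:
    dups = [d for d in validate_scenario(scenario) if d.startswith("duplicate")]
    if dups:
        raise ScenarioValidationError("; ".join(dups))


# ---------------------------------------------------------------------------
# CSV (one table per entity kind inside a directory)

_CSV_FILES = ("users.csv", "aeds.csv", "emergencies.csv")


def _scenario_to_csv(s: Scenario, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": u.id,
                "x": u.position[0],
                "y": u.position[1],
                "walking_speed": u.walking_speed,
                "battery_level": u.battery_level,
                "battery_consumption_rate": u.battery_consumption_rate,
                "available": u.available,
            }
            for u in s.users
        ],
        columns=[
            "id", "x", "y", "walking_speed", "battery_level",
            "battery_consumption_rate", "available",
        ],
    ).to_csv(directory / "users.csv", index=False)
    pd.DataFrame(
        [
            {"id": a.id, "x": a.position[0], "y": a.position[1], "functional": a.functional}
            for a in s.aeds
        ],
        columns=["id", "x", "y", "functional"],
    ).to_csv(directory / "aeds.csv", index=False)
    pd.DataFrame(
        [{"id": e.id, "x": e.position[0], "y": e.position[1]} for e in s.emergencies],
        columns=["id", "x", "y"],
    ).to_csv(directory / "emergencies.csv", index=False)
    meta = {"schema_version": SCHEMA_VERSION, "coordinate_system": s.coordinate_system}
    (directory / "scenario.json").write_text(json.dumps(meta, indent=2))
    if s.distance_matrix is not None:
        rows = [
            {"from_id": src, "to_id": dst, "distance_m": v}
            for src, row in s.distance_matrix.items()
            for dst, v in row.items()
        ]
        pd.DataFrame(rows, columns=["from_id", "to_id", "distance_m"]).to_csv(
            directory / "distance_matrix.csv", index=False
        )


def _scenario_from_csv(directory: Path) -> Scenario:
    for name in _CSV_FILES:
        if not (directory / name).exists():
            raise ScenarioFormatError(f"CSV scenario directory {directory} lacks {name}")
    users_df = pd.read_csv(directory / "users.csv", dtype={"id": str})
    aeds_df = pd.read_csv(directory / "aeds.csv", dtype={"id": str})
    em_df = pd.read_csv(directory / "emergencies.csv", dtype={"id": str})
    d: dict = {
        "users": [
            {
                "id": r.id,
                "position": [r.x, r.y],
                "walking_speed": r.walking_speed,
                "battery_level": r.battery_level,
                "battery_consumption_rate": r.battery_consumption_rate,
                "available": bool(r.available),
            }
            for r in users_df.itertuples()
        ],
        "aeds": [
            {"id": r.id, "position": [r.x, r.y], "functional": bool(r.functional)}
            for r in aeds_df.itertuples()
        ],
        "emergencies": [{"id": r.id, "position": [r.x, r.y]} for r in em_df.itertuples()],
    }
    meta_path = directory / "scenario.json"
    if meta_path.exists():
        d.update(json.loads(meta_path.read_text()))
    dm_path = directory / "distance_matrix.csv"
    if dm_path.exists():
        dm_df = pd.read_csv(dm_path, dtype={"from_id": str, "to_id": str})
        dm: dict[str, dict[str, float]] = {}
        for r in dm_df.itertuples():
            dm.setdefault(r.from_id, {})[r.to_id] = float(r.distance_m)
        d["distance_matrix"] = dm
    return _scenario_from_dict(d)


# ---------------------------------------------------------------------------
# GeoJSON


def _scenario_to_geojson(s: Scenario) -> dict:
    features = []
    for u in s.users:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(u.position)},
                "properties": {
                    "kind": "user",
                    "id": u.id,
                    "walking_speed": u.walking_speed,
                    "battery_level": u.battery_level,
                    "battery_consumption_rate": u.battery_consumption_rate,
                    "available": u.available,
                },
            }
        )
    for a in s.aeds:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(a.position)},
                "properties": {"kind": "aed", "id": a.id, "functional": a.functional},
            }
        )
    for e in s.emergencies:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(e.position)},
                "properties": {"kind": "emergency", "id": e.id},
            }
        )
    out = {
        "type": "FeatureCollection",
        "features": features,
        "coordinate_system": s.coordinate_system,
        "schema_version": SCHEMA_VERSION,
    }
    if s.distance_matrix is not None:
        out["distance_matrix"] = s.distance_matrix
    return out


def _scenario_from_geojson(d: Mapping) -> Scenario:
    if d.get("type") != "FeatureCollection":
        raise ScenarioFormatError("GeoJSON scenario must be a FeatureCollection")
    users, aeds, emergencies = [], [], []
    for feat in d.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ScenarioFormatError(f"non-Point feature in scenario: {feat!r}")
        props = dict(feat.get("properties") or {})
        props["position"] = geom.get("coordinates")
        kind = props.pop("kind", None)
        if kind == "user":
            users.append(props)
        elif kind == "aed":
            aeds.append(props)
        elif kind == "emergency":
            emergencies.append(props)
        else:
            raise ScenarioFormatError(f"feature with unknown kind {kind!r}: {feat!r}")
    return _scenario_from_dict(
        {
            "users": users,
            "aeds": aeds,
            "emergencies": emergencies,
            "coordinate_system": d.get("coordinate_system", "planar_m"),
            "distance_matrix": d.get("distance_matrix"),
        }
    )


# ---------------------------------------------------------------------------
# public I/O


def _infer_format(path: Path) -> str:
    if path.is_dir() or path.suffix == "":
        return "csv"
    if path.suffix == ".geojson":
        return "geojson"
    return "json"


def load_scenario(path: str | Path, format: str | None = None) -> Scenario:
    """Load and validate a scenario from JSON, a CSV directory, or GeoJSON."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _scenario_from_csv(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ScenarioFormatError(f"{path}: not valid JSON: {exc}") from exc
    if fmt == "geojson":
        return _scenario_from_geojson(d)
    if fmt == "json":
        return _scenario_from_dict(d)
    raise ValueError(f"unknown scenario format {fmt!r}")


def save_scenario(scenario: Scenario, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _scenario_to_csv(scenario, path)
    elif fmt == "geojson":
        path.write_text(json.dumps(_scenario_to_geojson(scenario), indent=2))
    elif fmt == "json":
        path.write_text(json.dumps(_scenario_to_dict(scenario), indent=2))
    else:
        raise ValueError(f"unknown scenario format {fmt!r}")


def save_matches(match_set: MatchSet, path: str | Path, format: str | None = None) -> None:
    """Write a solution with one record per match plus a summary block (JSON)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "json")
    records = [
        {
            "user_id": m.user_id,
            "aed_id": m.aed_id,
            "emergency_id": m.emergency_id,
            "travel_time": m.travel_time,
        }
        for m in match_set.matches
    ]
    if fmt == "json":
        payload = {
            "matches": records,
            "summary": {
                "n_matches": len(match_set),
                "total_match_time": match_set.total_match_time,
                "per_emergency_counts": match_set.per_emergency_counts,
                "unique_emergencies_covered": match_set.unique_emergencies_covered,
            },
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "csv":
        pd.DataFrame(
            records, columns=["user_id", "aed_id", "emergency_id", "travel_time"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown matches format {fmt!r}")


def load_matches(path: str | Path, format: str | None = None) -> MatchSet:
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        records = json.loads(path.read_text())["matches"]
    elif fmt == "csv":
        df = pd.read_csv(path, dtype={"user_id": str, "aed_id": str, "emergency_id": str})
        records = df.to_dict("records")
    else:
        raise ValueError(f"unknown matches format {fmt!r}")
    return MatchSet(
        [
            Match(
                user_id=str(r["user_id"]),
                aed_id=str(r["aed_id"]),
                emergency_id=str(r["emergency_id"]),
                travel_time=float(r["travel_time"]),
            )
            for r in records
        ]
    )
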