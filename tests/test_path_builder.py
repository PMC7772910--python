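import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surf.path_builder import (
    DistanceProvider,
    battery_feasible,
    enumerate_paths,
    powered_time,
    provider_for,
    radius_select,
    travel_time,
)
from surf.scenario_model import AED, Emergency, Scenario

from conftest import make_user


def test_travel_time_is_route_distance_over_speed():
    provider = DistanceProvider()
    user = make_user("u1", (0.0, 0.0), speed=1.2)
    aed = AED("a1", (60.0, 0.0))
    em = Emergency("e1", (120.0, 0.0))
    # 60 m to the AED plus 60 m onward at 1.2 m/s
    assert travel_time(user, aed, em, provider) == pytest.approx(100.0)


def test_travel_time_zero_when_collocated():
    provider = DistanceProvider()
    user = make_user("u1", (5.0, 5.0))
    assert travel_time(user, AED("a1", (5.0, 5.0)), Emergency("e1", (5.0, 5.0)), provider) == 0.0


def test_matrix_mode_uses_route_not_straight_line():
    """A 100 m straight-line separation can be a 600 m walk; the matrix wins."""
    user = make_user("u1", (0.0, 0.0), speed=1.0)
    aed = AED("a1", (0.0, 0.0))
    em = Emergency("e1", (100.0, 0.0))
    matrix = {"u1": {"a1": 0.0}, "a1": {"e1": 600.0}}
    provider = DistanceProvider(mode="matrix", matrix=matrix)
    assert travel_time(user, aed, em, provider) == pytest.approx(600.0)
    # while the radius baseline would still have selected this user
    assert radius_select([user], em, radius=500.0) == [user]


def test_matrix_mode_missing_entry_is_configuration_error():
    from surf.path_builder import DistanceConfigurationError

    provider = DistanceProvider(mode="matrix", matrix={"u1": {}})
    with pytest.raises(DistanceConfigurationError):
        provider.distance("u1", (0, 0), "a9", (1, 1))


def test_manhattan_grid_distance():
    provider = DistanceProvider(mode="manhattan_grid")
    assert provider.distance("p", (0.0, 0.0), "q", (30.0, 40.0)) == pytest.approx(70.0)
    snapped = DistanceProvider(mode="manhattan_grid", grid_spacing=100.0)
    assert snapped.distance("p", (0.0, 0.0), "q", (130.0, 0.0)) == pytest.approx(100.0)


def test_geographic_coordinates_use_haversine():
    provider = DistanceProvider(coordinate_system="geographic")
    # one degree of latitude is ~111.2 km
    d = provider.distance("p", (0.0, 0.0), "q", (0.0, 1.0))
    assert d == pytest.approx(111_195, rel=1e-3)


@pytest.mark.parametrize(
    "level,rate,expected", [(50.0, 0.05, 1000.0), (0.0, 0.01, 0.0), (100.0, 0.1, 1000.0)]
)
def test_powered_time(level, rate, expected):
    u = make_user("u1", (0.0, 0.0), level=level, rate=rate)
    assert powered_time(u) == pytest.approx(expected)


def test_powered_time_rejects_nonpositive_rate():
    u = make_user("u1", (0.0, 0.0), rate=0.01)
    bad = u.__class__(**{**u.__dict__, "battery_consumption_rate": 0.0})
    with pytest.raises(ValueError):
        powered_time(bad)


@pytest.mark.parametrize(
    "travel,expected", [(999.0, True), (1000.0, True), (1001.0, False)]
)
def test_battery_feasible_boundary_is_inclusive(travel, expected):
    u = make_user("u1", (0.0, 0.0), level=50.0, rate=0.05)  # powered for 1000 s
    assert battery_feasible(u, travel) is expected


def test_enumerate_paths_combinatorics(tiny_scenario):
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    assert ps.size == 3 * 2 * 2
    assert ps.max_edge_weight == pytest.approx(max(ps.travel_time) + 1.0)
    # exactly one path per triple, in lexicographic id order
    triples = {(p.user_id, p.aed_id, p.emergency_id) for p in ps.paths}
    assert len(triples) == 12


def test_enumerate_paths_skips_unavailable_and_broken(tiny_scenario):
    tiny_scenario.users[1] = make_user("u2", (100.0, 0.0), available=False)
    tiny_scenario.aeds[0] = AED("a1", (50.0, 0.0), functional=False)
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    assert ps.size == 2 * 1 * 2
    assert "u2" not in ps.user_ids and "a1" not in ps.aed_ids


def test_enumerate_paths_empty_when_no_emergency(tiny_scenario):
    tiny_scenario.emergencies = []
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    assert ps.size == 0


@settings(max_examples=30, deadline=None)
@given(
    n=st.integers(0, 5),
    m=st.integers(0, 4),
    o=st.integers(0, 3),
    seed=st.integers(0, 10_000),
)
def test_path_count_and_sentinel_properties(n, m, o, seed):
    """|paths| = n*m*o always, and the sentinel strictly dominates every time."""
    rng = np.random.default_rng(seed)
    sc = Scenario(
        users=[
            make_user(f"u{i}", tuple(rng.uniform(0, 500, 2)), speed=rng.uniform(1, 2))
            for i in range(n)
        ],
        aeds=[AED(f"a{j}", tuple(rng.uniform(0, 500, 2))) for j in range(m)],
        emergencies=[Emergency(f"e{k}", tuple(rng.uniform(0, 500, 2))) for k in range(o)],
    )
    ps = enumerate_paths(sc, DistanceProvider())
    assert ps.size == n * m * o
    if ps.size:
        assert (ps.travel_time < ps.max_edge_weight).all()


def test_travel_time_monotone_in_walking_speed():
    provider = DistanceProvider()
    aed = AED("a1", (60.0, 0.0))
    em = Emergency("e1", (120.0, 0.0))
    times = [
        travel_time(make_user("u1", (0.0, 0.0), speed=s), aed, em, provider)
        for s in (0.8, 1.0, 1.4, 2.0)
    ]
    assert times == sorted(times, reverse=True)


def test_battery_feasibility_monotone_in_travel_time():
    u = make_user("u1", (0.0, 0.0), level=10.0, rate=0.01)  # 1000 s powered
    assert not battery_feasible(u, 1500.0)
    assert not battery_feasible(u, 2000.0)  # worse time stays infeasible


def test_radius_select_boundary():
    em = Emergency("e1", (0.0, 0.0))
    inside = make_user("u1", (499.0, 0.0))
    outside = make_user("u2", (501.0, 0.0))
    assert radius_select([outside, inside], em, 500.0) == [inside]


def test_provider_for_prefers_matrix(tiny_scenario):
    assert provider_for(tiny_scenario).mode == "euclidean"
    tiny_scenario.distance_matrix = {}
    assert provider_for(tiny_scenario).mode == "matrix"
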