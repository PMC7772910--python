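import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from surf.scenario_model import (
    AED,
    Emergency,
    MatchSet,
    Scenario,
    User,
    matchset_diagnostics,
)


def make_user(uid, pos, speed=1.2, level=100.0, rate=0.01, available=True):
    return User(
        id=uid,
        position=pos,
        walking_speed=speed,
        battery_level=level,
        battery_consumption_rate=rate,
        available=available,
    )


@pytest.fixture
def tiny_scenario():
    """3 users, 2 AEDs, 2 emergencies on a 1 km line; everything feasible."""
    users = [
        make_user("u1", (0.0, 0.0)),
        make_user("u2", (100.0, 0.0)),
        make_user("u3", (200.0, 0.0)),
    ]
    aeds = [AED("a1", (50.0, 0.0)), AED("a2", (150.0, 0.0))]
    emergencies = [Emergency("e1", (120.0, 0.0)), Emergency("e2", (400.0, 0.0))]
    return Scenario(users=users, aeds=aeds, emergencies=emergencies)


def assert_valid_solution(match_set: MatchSet, scenario: Scenario, horizon=None):
    """Solution invariants common to every solver."""
    assert matchset_diagnostics(match_set) == []
    user_ids = {u.id for u in scenario.users if u.available}
    aed_ids = {a.id for a in scenario.aeds if a.functional}
    em_ids = {e.id for e in scenario.emergencies}
    for m in match_set:
        assert m.user_id in user_ids
        assert m.aed_id in aed_ids
        assert m.emergency_id in em_ids
        user = scenario.user(m.user_id)
        assert user.battery_level / user.battery_consumption_rate >= m.travel_time
        if horizon is not None:
            assert m.travel_time <= horizon + 1e-9
    assert match_set.total_match_time == pytest.approx(
        sum(m.travel_time for m in match_set)
    )
    assert sum(match_set.per_emergency_counts.values()) == len(match_set)
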