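import numpy as np
import pytest

from surf.ilp_matcher import (
    brute_force_match,
    build_ilp,
    export_lp,
    lexicographic_value,
    match_ilp,
    objective_value,
    set_emergency_cap,
    solve_ilp,
    summarize,
)
from surf.path_builder import DistanceProvider, enumerate_paths, provider_for
from surf.scenario_model import AED, Emergency, Match, MatchSet, Scenario, SolverOptions
from surf.synthetic_scenarios import (
    GeneratorSpec,
    generate_scenario,
    special_case_scenario,
)

from conftest import assert_valid_solution, make_user


def small_instance(seed, feasible_only=False):
    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(
        n_users=int(rng.integers(1, 6)),
        n_aeds=int(rng.integers(1, 4)),
        n_emergencies=int(rng.integers(1, 4)),
        battery_level_range=(80.0, 100.0) if feasible_only else (20.0, 100.0),
        battery_rate_range=(0.002, 0.004) if feasible_only else (0.002, 0.02),
        seed=seed,
    )
    return generate_scenario(spec)


def test_build_ilp_variable_and_model_shape(tiny_scenario):
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    model = build_ilp(ps, SolverOptions(method="ilp", horizon=10_000.0))
    assert model.n_variables == 12  # 3 users * 2 AEDs * 2 emergencies, all feasible
    assert (model.inverted_times >= 1.0).all()
    assert model.big_time == pytest.approx(ps.max_edge_weight)


def test_build_ilp_minimal_model():
    sc = Scenario(
        users=[make_user("u1", (0.0, 0.0))],
        aeds=[AED("a1", (10.0, 0.0))],
        emergencies=[Emergency("e1", (20.0, 0.0))],
    )
    ps = enumerate_paths(sc, DistanceProvider())
    model = build_ilp(ps, SolverOptions(method="ilp"))
    assert model.n_variables == 1
    ms = solve_ilp(model)
    assert len(ms) == 1


def test_build_ilp_empty_when_all_infeasible(tiny_scenario):
    for i, u in enumerate(tiny_scenario.users):
        tiny_scenario.users[i] = make_user(u.id, u.position, level=0.001, rate=1.0)
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    model = build_ilp(ps, SolverOptions(method="ilp"))
    assert model.is_empty
    assert len(solve_ilp(model)) == 0


def test_solve_ilp_prefers_faster_user_for_contested_aed():
    sc = Scenario(
        users=[make_user("u_far", (0.0, 0.0)), make_user("u_near", (24.0, 0.0))],
        aeds=[AED("a1", (120.0, 0.0))],
        emergencies=[Emergency("e1", (120.0, 0.0))],
    )
    ms = match_ilp(sc, DistanceProvider(), SolverOptions(method="ilp"))
    assert [m.user_id for m in ms] == ["u_near"]


def test_solve_ilp_matches_disjoint_pairs_fully():
    sc = Scenario(
        users=[make_user("u1", (0.0, 0.0)), make_user("u2", (1000.0, 0.0))],
        aeds=[AED("a1", (10.0, 0.0)), AED("a2", (1010.0, 0.0))],
        emergencies=[Emergency("e1", (20.0, 0.0)), Emergency("e2", (1020.0, 0.0))],
    )
    ms = match_ilp(sc, DistanceProvider(), SolverOptions(method="ilp"))
    assert len(ms) == 2


@pytest.mark.parametrize("fairness", [False, True])
@pytest.mark.parametrize("cap", [None, 2])
def test_ilp_equals_brute_force_oracle(fairness, cap):
    """Objective equality against exhaustive search on 30 seeded instances."""
    for seed in range(30):
        sc = small_instance(seed)
        ps = enumerate_paths(sc, provider_for(sc))
        opts = SolverOptions(method="ilp", fairness=fairness, cap=cap, horizon=3000.0)
        ilp = solve_ilp(build_ilp(ps, opts))
        oracle = brute_force_match(ps, opts)
        big = ps.subset(ps.feasible_mask(opts.horizon)).max_edge_weight
        k_ilp = lexicographic_value(ilp, big, ps.emergency_ids)
        k_oracle = lexicographic_value(oracle, big, ps.emergency_ids)
        if fairness:
            assert k_ilp[0] == k_oracle[0], f"seed {seed}: MinPair differs"
        assert k_ilp[1] == pytest.approx(k_oracle[1]), f"seed {seed}"
        assert_valid_solution(ilp, sc, horizon=opts.horizon)


def test_fairness_splits_special_case_two_per_emergency():
    sc = special_case_scenario()
    prov = provider_for(sc)
    greedy = match_ilp(sc, prov, SolverOptions(method="ilp"))
    fair = match_ilp(sc, prov, SolverOptions(method="ilp", fairness=True))
    assert greedy.per_emergency_counts == {"e1": 4}
    assert greedy.total_match_time == pytest.approx(240.0)
    assert fair.per_emergency_counts == {"e1": 2, "e2": 2}
    assert fair.total_match_time == pytest.approx(260.0)


def test_fairness_noop_with_single_emergency():
    sc = small_instance(3)
    sc.emergencies = sc.emergencies[:1]
    prov = provider_for(sc)
    plain = match_ilp(sc, prov, SolverOptions(method="ilp"))
    fair = match_ilp(sc, prov, SolverOptions(method="ilp", fairness=True))
    assert plain == fair


def test_weighted_fairness_agrees_on_min_pair():
    sc = special_case_scenario()
    prov = provider_for(sc)
    lex = match_ilp(sc, prov, SolverOptions(method="ilp", fairness=True))
    weighted = match_ilp(
        sc, prov, SolverOptions(method="ilp", fairness=True, fairness_mode="weighted")
    )
    assert min(lex.per_emergency_counts.values()) == min(
        weighted.per_emergency_counts.values()
    )


def test_emergency_cap_binds():
    sc = generate_scenario(GeneratorSpec(10, 10, 1, seed=5,
                                         battery_level_range=(90.0, 100.0),
                                         battery_rate_range=(0.002, 0.003)))
    prov = provider_for(sc)
    uncapped = match_ilp(sc, prov, SolverOptions(method="ilp", horizon=10_000.0))
    assert len(uncapped) == 10
    ps = enumerate_paths(sc, prov)
    model = build_ilp(ps, SolverOptions(method="ilp", horizon=10_000.0))
    set_emergency_cap(model, 3)
    capped = solve_ilp(model)
    assert len(capped) == 3
    # a cap above the feasible count changes nothing
    model2 = build_ilp(ps, SolverOptions(method="ilp", horizon=10_000.0))
    set_emergency_cap(model2, 50)
    assert solve_ilp(model2) == uncapped


def test_cap_one_with_fairness_covers_both_emergencies():
    sc = special_case_scenario()
    ms = match_ilp(
        sc, provider_for(sc), SolverOptions(method="ilp", fairness=True, cap=1)
    )
    assert ms.per_emergency_counts == {"e1": 1, "e2": 1}


def test_brute_force_guard_refuses_large_instances():
    sc = generate_scenario(GeneratorSpec(10, 7, 3, seed=0))
    ps = enumerate_paths(sc, provider_for(sc))
    with pytest.raises(ValueError, match="guard"):
        brute_force_match(ps, SolverOptions(method="ilp"))


def test_brute_force_empty_path_set():
    sc = Scenario()
    ps = enumerate_paths(sc, DistanceProvider())
    assert len(brute_force_match(ps, SolverOptions(method="ilp"))) == 0


def test_match_count_monotone_when_adding_resources():
    """On fully feasible instances, extra users or AEDs never lose matches."""
    for seed in range(10):
        sc = small_instance(seed, feasible_only=True)
        prov = provider_for(sc)
        opts = SolverOptions(method="ilp", horizon=50_000.0)
        base = len(match_ilp(sc, prov, opts))
        sc_u = Scenario(
            users=sc.users + [make_user("zz_new", (500.0, 500.0), level=100.0, rate=0.002)],
            aeds=sc.aeds,
            emergencies=sc.emergencies,
        )
        sc_a = Scenario(
            users=sc.users,
            aeds=sc.aeds + [AED("zz_aed", (500.0, 500.0))],
            emergencies=sc.emergencies,
        )
        assert len(match_ilp(sc_u, prov, opts)) >= base
        assert len(match_ilp(sc_a, prov, opts)) >= base


def test_summarize_counts_and_coverage():
    ms = MatchSet(
        [
            Match("u1", "a1", "e1", 10.0),
            Match("u2", "a2", "e1", 20.0),
            Match("u3", "a3", "e2", 30.0),
        ]
    )
    s = summarize(ms)
    assert s["n_matches"] == 3
    assert s["total_match_time"] == pytest.approx(60.0)
    assert s["per_emergency_counts"] == {"e1": 2, "e2": 1}
    assert s["unique_emergencies_covered"] == 2
    empty = summarize(MatchSet([]))
    assert empty["n_matches"] == 0 and empty["unique_emergencies_covered"] == 0


def test_export_lp_writes_readable_model(tiny_scenario, tmp_path):
    ps = enumerate_paths(tiny_scenario, DistanceProvider())
    model = build_ilp(ps, SolverOptions(method="ilp", horizon=10_000.0))
    out = tmp_path / "model.lp"
    export_lp(model, out)
    text = out.read_text()
    assert text.startswith("Maximize")
    assert "user_u1" in text and "aed_a1" in text and "Binary" in text
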