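"""surf: matching volunteer responders and AEDs to cardiac-arrest emergencies.

The package pairs registered volunteer responders with automated external
defibrillators (AEDs) and simultaneous out-of-hospital cardiac arrests so
that every selected responder carries a uniquely assigned AED and the
time-to-patient is minimized. Three interchangeable solvers are provided:
iterative Hungarian matching (``bm``), a full integer linear program
(``ilp``) and the travel-time-sliced preprocessed ILP (``ppilp``), with an
optional max-min fairness objective across emergencies.
"""

from .scenario_model import (
    AED,
    Emergency,
    Match,
    MatchSet,
    Scenario,
    SolverOptions,
    User,
    load_matches,
    load_scenario,
    matchset_diagnostics,
    save_matches,
    save_scenario,
    validate_scenario,
)
from .path_builder import (
    CandidatePath,
    DistanceProvider,
    PathSet,
    battery_feasible,
    enumerate_paths,
    powered_time,
    provider_for,
    radius_select,
    travel_time,
)
from .bipartite_matcher import match_bipartite
from .ilp_matcher import (
    brute_force_match,
    build_ilp,
    match_ilp,
    solve_ilp,
    summarize,
)
from .preprocessed_ilp import match_preprocessed
from .synthetic_scenarios import (
    GeneratorSpec,
    generate_scenario,
    generate_suite,
    special_case_scenario,
)

__version__ = "0.1.0"

#: method name -> solver callable(scenario, provider, options) -> MatchSet
SOLVERS = {
    "bm": match_bipartite,
    "ilp": match_ilp,
    "ppilp": match_preprocessed,
}


def match(scenario, options=None, provider=None):
    """Solve one scenario with the method named in ``options.method``."""
    options = options or SolverOptions()
    provider = provider or provider_for(scenario)
    return SOLVERS[options.method](scenario, provider, options)
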