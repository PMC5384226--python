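from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import linprog

from ufba.errors import DataError, InfeasibleDataError
from ufba.model_core import stoichiometric_matrix
from ufba.relaxation import (
    add_relaxation_sinks,
    finalize_relaxation,
    fix_relaxation_magnitudes,
    relax,
    solve_relaxation,
)
from ufba.synthetic import make_random_instance, make_scenario, make_toy_network
from ufba.timecourse import RateEstimate
from ufba.ufba_build import build_ufba_model

from conftest import build_model


def _rate(met, slope, half=0.05, compartment="c"):
    return RateEstimate(metabolite_id=met, state_index=1, slope=slope,
                        b1=slope - half, b2=slope + half,
                        significant=not (slope - half <= 0 <= slope + half),
                        compartment=compartment)


def _oracle(model, candidates, big_m=1000.0):
    """Exhaustive subset-feasibility search on the sink-free model."""
    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    lb = np.array([model.reactions.get_by_id(r).lower_bound for r in rxn_ids])
    ub = np.array([model.reactions.get_by_id(r).upper_bound for r in rxn_ids])
    idx = {m: i for i, m in enumerate(met_ids)}
    bounds = list(zip(lb, ub))
    c = np.zeros(len(rxn_ids))

    def feasible(sub):
        mask = np.zeros(len(met_ids), bool)
        for m in sub:
            mask[idx[m]] = True
        kwargs = dict(c=c, A_eq=S[~mask], b_eq=np.zeros(int((~mask).sum())),
                      bounds=bounds, method="highs")
        if mask.any():
            rows = S[mask]
            kwargs["A_ub"] = np.vstack([rows, -rows])
            kwargs["b_ub"] = np.full(2 * rows.shape[0], big_m)
        return linprog(**kwargs).status == 0

    for k in range(len(candidates) + 1):
        feas = {frozenset(s) for s in combinations(candidates, k) if feasible(s)}
        if feas:
            return k, feas
    return None, set()


def _chain_instance():
    """A -> B -> C, closed, with only A measured (depleting): the flux must
    exit somewhere unmeasured, so exactly one node needs relaxing."""
    m = build_model(
        "chain",
        [("A", "c"), ("B", "c"), ("C", "c")],
        [("R1", {"A": -1, "B": 1}, 0, 10), ("R2", {"B": -1, "C": 1}, 0, 10)],
    )
    return build_ufba_model(m, [_rate("A", -1.0)])


def test_chain_matches_brute_force():
    u = _chain_instance()
    base = u.model.copy()
    problem = add_relaxation_sinks(u, case=1)
    result = solve_relaxation(problem)
    k, optimal = _oracle(base, sorted(problem.unmeasured))
    assert min(len(s.support) for s in result.iterations) == k == 1
    assert all(frozenset(s.support) in optimal for s in result.iterations)
    # depleting A pushes material downstream: every optimum accumulates
    assert all(list(s.support.values()) == ["up"] for s in result.iterations)


def test_feasible_model_needs_no_relaxation(chain_model):
    # measured depletion of A matched by measured accumulation of C: the
    # chain itself balances, no relaxation required
    u = build_ufba_model(chain_model, [_rate("A", -1.0), _rate("C", 1.0, compartment="e")])
    u, result = relax(u)
    assert result.final == {}
    assert u.relaxation_sinks == {}


def test_infeasible_data_raises():
    # measured production of a metabolite nothing can produce
    m = build_model("dead", [("A", "c"), ("B", "c")],
                    [("R1", {"A": -1, "B": 1}, 0, 10)])
    u = build_ufba_model(m, [_rate("A", 1.0)])
    u.model.reactions.ACC_A.bounds = (0.95, 1.05)
    with pytest.raises(InfeasibleDataError, match="inconsistent with stoichiometry"):
        relax(u)


def test_case_validation(chain_model):
    u = build_ufba_model(chain_model, [_rate("A", -1.0)])
    with pytest.raises(DataError, match="case must be"):
        add_relaxation_sinks(u, case=7)


def test_integer_cuts_enumerate_distinct_supports():
    sc = make_scenario("twin_pathway", seed=0)
    # closed twin pathway: a_c depletes into x1/x2; either twin end works
    u = build_ufba_model(sc.model, [_rate("a_c", -1.0)])
    problem = add_relaxation_sinks(u, case=1)
    result = solve_relaxation(problem)
    supports = [frozenset(s.support) for s in result.iterations]
    assert len(supports) == len(set(supports))  # cuts forbid repetition
    assert set().union(*supports) == {"x1_c", "x2_c"}
    assert all(len(s) == 1 for s in supports)
    # tallies count each node once
    assert result.tally == {"x1_c": 1, "x2_c": 1}


def test_case1_cardinality_never_exceeds_case2():
    for seed in (3, 11, 19):
        model, rates, _ = make_random_instance(seed)
        u1 = build_ufba_model(model, rates)
        p1 = add_relaxation_sinks(u1, case=1)
        r1 = solve_relaxation(p1)
        k1 = min(len(s.support) for s in r1.iterations)
        u2 = build_ufba_model(model, rates)
        p2 = add_relaxation_sinks(u2, case=2)
        r2 = solve_relaxation(p2)
        k2 = min(len(s.support) for s in r2.iterations)
        assert k1 <= k2


def test_qp_cases_split_symmetric_twins():
    """Σd² strictly prefers the even split across symmetric outlets."""
    sc = make_scenario("twin_pathway", seed=0)
    u = build_ufba_model(sc.model, [_rate("a_c", -1.0)])
    problem = add_relaxation_sinks(u, case=4)
    result = solve_relaxation(problem)
    assert len(result.iterations) == 1
    d = result.iterations[0].d
    assert d["x1_c"] == pytest.approx(d["x2_c"], rel=1e-3)
    assert d["x1_c"] + d["x2_c"] == pytest.approx(1.0, abs=0.11)


@pytest.mark.parametrize("case", [2, 3, 5])
def test_all_cases_solve_the_chain(case):
    u = _chain_instance()
    u, result = relax(u, case=case)
    assert result.final
    # retained sinks keep the model feasible
    with u.model as m:
        m.slim_optimize()
        assert m.solver.status == "optimal"


def test_finalize_prunes_unretained_sinks():
    sc = make_scenario("twin_pathway", seed=0)
    u = build_ufba_model(sc.model, [_rate("a_c", -1.0)])
    problem = add_relaxation_sinks(u, case=1)
    result = finalize_relaxation(problem, solve_relaxation(problem))
    assert len(result.final) == 1
    kept = set(result.final)
    assert set(u.relaxation_sinks) == kept
    sink_rxns = [r.id for r in u.model.reactions if r.id.startswith("RELAX_")]
    assert len(sink_rxns) == 1


def test_magnitude_fixing_caps_at_scale():
    u = _chain_instance()
    problem = add_relaxation_sinks(u, case=1)
    result = finalize_relaxation(problem, solve_relaxation(problem))
    fix_relaxation_magnitudes(u, result, scale=1.5)
    (met,) = result.final
    d_star = result.d_star[met]
    assert d_star == pytest.approx(0.95, abs=1e-6)  # lower CI end of the A rate
    (sink_id,) = u.relaxation_sinks[met]
    assert u.model.reactions.get_by_id(sink_id).bounds == pytest.approx((0.0, 1.5 * d_star))


def test_exo_preference_retains_extracellular_node():
    model = make_toy_network("pool_depletion")
    rates = [_rate("cit_e", -1.0, compartment="e"), _rate("mal_c", -2.0),
             _rate("mal_e", 0.5, compartment="e"), _rate("asp_e", 0.15, compartment="e")]
    u = build_ufba_model(model, rates)
    u, result = relax(u, case=1, exo_preference=True)
    assert result.final == {"lac_e": "up"}


def test_relaxation_determinism():
    model, rates, _ = make_random_instance(21)
    runs = []
    for _ in range(2):
        u = build_ufba_model(model, rates)
        u, result = relax(u, seed=7)
        runs.append((result.final, result.d_star, result.scaled_bounds,
                     [s.support for s in result.iterations]))
    assert runs[0] == runs[1]
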