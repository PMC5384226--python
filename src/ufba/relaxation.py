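"""Metabolite-node relaxation: parsimonious deviation from steady state.

A closed model with measured accumulation bounds is usually infeasible,
because unmeasured metabolites that genuinely change are pinned at steady
state.  For every unmeasured metabolite, two sink reactions are added — an
"up" sink ({met: −1}, flux ≥ 0 = the pool accumulates) and a "down" sink
({met: +1}, flux ≥ 0 = the pool depletes).  An optimization then decides
the smallest deviation from steady state that restores feasibility; five
parsimony criteria are implemented:

Case 1 (MILP)  minimize the number of relaxed nodes (default; minimizes
               the gain in degrees of freedom),
Case 2 (LP)    minimize the summed magnitude of sink fluxes Σ|d|,
Case 3 (LP)    Case 2 plus the summed magnitude of internal fluxes Σ|v|,
Case 4 (QP)    minimize Σ d²,
Case 5 (QP)    Case 4 plus Σ v².

Because alternative optima are common (especially for Case 1), the chosen
problem is re-solved repeatedly under integer cuts that exclude previously
found supports (100 iterations by default; each iteration is limited by a
relative-gap / wall-time criterion).  Appearance frequencies are tallied
and a final frequency-weighted optimization picks the retained nodes
(cost 1 − f + ε per node, with an optional discount that prefers
extracellular nodes).  Finally the summed flux through the retained sinks
is minimized and each sink is capped at ``scale`` × its minimal flux
(1.5× by default; 1× over-constrains downstream sampling).

MILP and LP solves run on the model's optlang/GLPK problem; the strictly
convex QP cases are assembled as sparse matrices and solved with OSQP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

import cobra

from ufba.errors import DataError, InfeasibleDataError, SolverError
from ufba.model_core import DEFAULT_BOUND, stoichiometric_matrix
from ufba.ufba_build import (
    RELAX_DOWN_PREFIX,
    RELAX_UP_PREFIX,
    UnsteadyModel,
)

#: A sink flux above this is considered a genuine deviation from steady state.
RELAX_TOL = 1e-9
#: ε in the finalization cost 1 − f + ε: zero-frequency nodes keep positive
#: cost so cardinality still dominates frequency.
FINAL_EPS = 1e-3
#: Weight of the auxiliary binary term added to LP objectives so supports
#: are identifiable for integer cuts without perturbing the optimum.
LP_BINARY_EPS = 1e-4


@dataclass
class RelaxationProblem:
    """A closed model with up/down sinks on every unmeasured metabolite.

    ``m`` counts unmeasured metabolites (sink pairs); ``n`` counts
    intracellular reactions (everything that is not an accumulation,
    sink, efflux or reserve pseudo-reaction).
    """

    umodel: UnsteadyModel
    unmeasured: list = field(default_factory=list)
    m: int = 0
    n: int = 0
    case: int = 1
    iterations: int = 100
    gap_tol: float = 1e-6
    time_limit: float = 45.0
    exo_preference: bool = False
    extracellular_compartment: str = "e"
    big_m: float = DEFAULT_BOUND
    seed: int = 0


@dataclass
class IterationSolution:
    support: dict  # metabolite id -> direction ("up"/"down")
    objective: float
    d: dict = field(default_factory=dict)  # metabolite id -> net sink flux


@dataclass
class RelaxationResult:
    case: int
    iterations: list = field(default_factory=list)  # list[IterationSolution]
    tally: dict = field(default_factory=dict)  # metabolite id -> count
    n_iterations: int = 0
    final: dict = field(default_factory=dict)  # metabolite id -> direction
    d_star: dict = field(default_factory=dict)
    scaled_bounds: dict = field(default_factory=dict)
    objective_values: list = field(default_factory=list)

    @property
    def frequencies(self) -> dict:
        if self.n_iterations == 0:
            return {}
        return {k: v / self.n_iterations for k, v in self.tally.items()}

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "iterations": [
                {"support": s.support, "objective": s.objective, "d": s.d}
                for s in self.iterations
            ],
            "tally": self.tally,
            "n_iterations": self.n_iterations,
            "final": self.final,
            "d_star": self.d_star,
            "scaled_bounds": self.scaled_bounds,
            "objective_values": self.objective_values,
        }


def add_relaxation_sinks(
    umodel: UnsteadyModel,
    case: int = 1,
    iterations: int = 100,
    gap_tol: float = 1e-6,
    time_limit: float = 45.0,
    exo_preference: bool = False,
    extracellular_compartment: str = "e",
    big_m: float = DEFAULT_BOUND,
    seed: int = 0,
) -> RelaxationProblem:
    """Install up/down sinks for every unmeasured metabolite.

    Metabolites with an integrated measurement, an existing free efflux
    (FBA controls) or a reserve sink keep their treatment and get no
    relaxation sinks.
    """
    if case not in (1, 2, 3, 4, 5):
        raise DataError(f"relaxation case must be 1..5, got {case}")
    model = umodel.model
    skip = set(umodel.measured) | set(umodel.free_efflux) | set(umodel.reserves)
    unmeasured = []
    new_reactions = []
    for met in model.metabolites:
        if met.id in skip:
            continue
        up = cobra.Reaction(RELAX_UP_PREFIX + met.id, lower_bound=0.0, upper_bound=big_m)
        up.add_metabolites({met: -1.0})
        up.annotation["pseudo"] = "relaxation_up"
        down = cobra.Reaction(RELAX_DOWN_PREFIX + met.id, lower_bound=0.0, upper_bound=big_m)
        down.add_metabolites({met: 1.0})
        down.annotation["pseudo"] = "relaxation_down"
        new_reactions.extend([up, down])
        unmeasured.append(met.id)
        umodel.relaxation_sinks[met.id] = [up.id, down.id]
    model.add_reactions(new_reactions)
    pseudo = umodel.pseudo_reaction_ids()
    n_internal = sum(1 for r in model.reactions if r.id not in pseudo)
    return RelaxationProblem(
        umodel=umodel,
        unmeasured=unmeasured,
        m=len(unmeasured),
        n=n_internal,
        case=case,
        iterations=iterations,
        gap_tol=gap_tol,
        time_limit=time_limit,
        exo_preference=exo_preference,
        extracellular_compartment=extracellular_compartment,
        big_m=big_m,
        seed=seed,
    )


def _check_base_feasible(problem: RelaxationProblem) -> None:
    model = problem.umodel.model
    with model:
        model.objective = model.problem.Objective(0)
        model.slim_optimize()
        status = model.solver.status
    if status != "optimal":
        raise InfeasibleDataError(
            "data inconsistent with stoichiometry: the measured rates cannot "
            "be balanced even with every relaxation sink open "
            f"(solver status {status!r})"
        )


class _MilpMachine:
    """Binary support variables + coupling d <= M*y on a working copy."""

    def __init__(self, problem: RelaxationProblem, model: cobra.Model):
        self.problem = problem
        self.model = model
        iface = model.problem
        self.y = {}
        constraints = []
        for met_id in problem.unmeasured:
            up_id, down_id = problem.umodel.relaxation_sinks[met_id][:2]
            up = model.reactions.get_by_id(up_id)
            down = model.reactions.get_by_id(down_id)
            y = iface.Variable(f"relax_ind_{met_id}", type="binary")
            self.y[met_id] = y
            constraints.append(
                iface.Constraint(
                    up.flux_expression + down.flux_expression - problem.big_m * y,
                    ub=0.0,
                    name=f"relax_couple_{met_id}",
                )
            )
        model.add_cons_vars(list(self.y.values()) + constraints)
        cfg = model.solver.configuration
        cfg.timeout = max(1, int(round(problem.time_limit)))
        cfg.verbosity = 0
        self._n_cuts = 0

    def sink_flux(self, met_id: str) -> tuple[float, float]:
        up_id, down_id = self.problem.umodel.relaxation_sinks[met_id][:2]
        up = self.model.reactions.get_by_id(up_id).flux
        down = self.model.reactions.get_by_id(down_id).flux
        return up, down

    def support(self) -> dict:
        out = {}
        for met_id, y in self.y.items():
            if y.primal is None or y.primal < 0.5:
                continue
            up, down = self.sink_flux(met_id)
            out[met_id] = "up" if up >= down else "down"
        return out

    def d_total(self) -> float:
        return sum(sum(self.sink_flux(m)) for m in self.y)

    def add_integer_cut(self, support) -> None:
        iface = self.model.problem
        expr = sum(self.y[m] for m in support)
        self._n_cuts += 1
        self.model.add_cons_vars(
            [iface.Constraint(expr, ub=len(support) - 1, name=f"relax_cut_{self._n_cuts}")]
        )


def _abs_flux_terms(problem: RelaxationProblem, model: cobra.Model):
    """t_i >= |v_i| auxiliaries for every intracellular reaction."""
    iface = model.problem
    pseudo = problem.umodel.pseudo_reaction_ids()
    ts = []
    cons = []
    for rxn in model.reactions:
        if rxn.id in pseudo:
            continue
        t = iface.Variable(f"absflux_{rxn.id}", lb=0)
        ts.append(t)
        cons.append(iface.Constraint(rxn.flux_expression - t, ub=0, name=f"abs_p_{rxn.id}"))
        cons.append(iface.Constraint(-rxn.flux_expression - t, ub=0, name=f"abs_n_{rxn.id}"))
    model.add_cons_vars(ts + cons)
    return ts


def _solve_qp(problem: RelaxationProblem, model: cobra.Model, sink_weights: dict | None = None):
    """Minimize weighted Σ f² over sink columns (+ Σ v² for Case 5) subject
    to S·v = 0 and flux bounds, via OSQP.  Returns flux dict or None."""
    import osqp

    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    lb = np.array([model.reactions.get_by_id(r).lower_bound for r in rxn_ids])
    ub = np.array([model.reactions.get_by_id(r).upper_bound for r in rxn_ids])
    w = np.zeros(n)
    sink_ids = {}
    for met_id in problem.unmeasured:
        for sid in problem.umodel.relaxation_sinks[met_id][:2]:
            sink_ids[sid] = met_id
    for j, rid in enumerate(rxn_ids):
        if rid in sink_ids:
            met_id = sink_ids[rid]
            w[j] = 1.0 if sink_weights is None else sink_weights.get(met_id, 1.0)
        elif problem.case == 5 and rid not in problem.umodel.pseudo_reaction_ids():
            w[j] = 1.0
    # tiny ridge keeps the problem strictly convex for OSQP
    P = sp.diags(2.0 * np.maximum(w, 1e-8), format="csc")
    q = np.zeros(n)
    A = sp.vstack([sp.csc_matrix(S), sp.identity(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P, q, A, l, u, verbose=False, eps_abs=1e-9, eps_rel=1e-9,
               max_iter=200000, polishing=True)
    res = prob.solve()
    if "solved" not in res.info.status:
        return None
    return dict(zip(rxn_ids, res.x))


def _qp_support(problem: RelaxationProblem, flux: dict, tol: float = 1e-6) -> dict:
    support = {}
    for met_id in problem.unmeasured:
        up_id, down_id = problem.umodel.relaxation_sinks[met_id][:2]
        up, down = flux[up_id], flux[down_id]
        if up + down > tol:
            support[met_id] = "up" if up >= down else "down"
    return support


def solve_relaxation(problem: RelaxationProblem) -> RelaxationResult:
    """Enumerate (near-)optimal relaxation supports and tally frequencies.

    Case 1 iterates the cardinality MILP under integer cuts, keeping only
    minimum-cardinality supports.  Cases 2–3 iterate the magnitude LP with
    auxiliary binaries solely to express support-exclusion cuts, stopping
    when the objective degrades beyond 0.1% relative.  Cases 4–5 are
    strictly convex in the sink fluxes and yield a single solution.

    Raises :class:`InfeasibleDataError` if the model is infeasible even
    with every sink open.
    """
    _check_base_feasible(problem)
    result = RelaxationResult(case=problem.case)
    if problem.m == 0:
        result.n_iterations = 1
        result.iterations.append(IterationSolution(support={}, objective=0.0))
        result.objective_values.append(0.0)
        return result

    if problem.case in (4, 5):
        model = problem.umodel.model.copy()
        flux = _solve_qp(problem, model)
        if flux is None:
            raise SolverError(f"OSQP failed on relaxation case {problem.case}")
        support = _qp_support(problem, flux)
        obj = sum(
            flux[sid] ** 2
            for met_id in problem.unmeasured
            for sid in problem.umodel.relaxation_sinks[met_id][:2]
        )
        d = {
            met_id: sum(flux[sid] for sid in problem.umodel.relaxation_sinks[met_id][:2])
            for met_id in support
        }
        result.iterations.append(IterationSolution(support=support, objective=obj, d=d))
        result.objective_values.append(obj)
        result.n_iterations = 1
        for met_id in support:
            result.tally[met_id] = 1
        return result

    model = problem.umodel.model.copy()
    machine = _MilpMachine(problem, model)
    iface = model.problem
    if problem.case == 1:
        objective_expr = sum(machine.y.values())
    else:
        d_expr = sum(
            model.reactions.get_by_id(sid).flux_expression
            for met_id in problem.unmeasured
            for sid in problem.umodel.relaxation_sinks[met_id][:2]
        )
        objective_expr = d_expr + LP_BINARY_EPS * sum(machine.y.values())
        if problem.case == 3:
            objective_expr = objective_expr + sum(_abs_flux_terms(problem, model))
    model.objective = iface.Objective(objective_expr, direction="min")

    first_obj = None
    for it in range(problem.iterations):
        model.slim_optimize()
        if model.solver.status != "optimal":
            if it == 0:
                raise SolverError(
                    f"relaxation case {problem.case} iteration 0: solver status "
                    f"{model.solver.status!r}"
                )
            break
        if problem.case == 1:
            obj = float(round(model.objective.value))
            degrade = first_obj is not None and obj > first_obj + 0.5
        else:
            obj = machine.d_total()
            degrade = first_obj is not None and obj > first_obj * (1 + 1e-3) + 1e-9
        if degrade:
            break
        if first_obj is None:
            first_obj = obj
        support = machine.support()
        d = {met_id: sum(machine.sink_flux(met_id)) for met_id in support}
        result.iterations.append(IterationSolution(support=dict(support), objective=obj, d=d))
        result.objective_values.append(obj)
        result.n_iterations += 1
        for met_id in support:
            result.tally[met_id] = result.tally.get(met_id, 0) + 1
        if not support:
            break
        machine.add_integer_cut(support)
    return result


def finalize_relaxation(problem: RelaxationProblem, result: RelaxationResult) -> RelaxationResult:
    """Frequency-weighted final optimization; prune non-retained sinks.

    Each unmeasured node j gets cost c_j = 1 − f_j + ε with f_j its tally
    frequency; with ``exo_preference`` the cost of extracellular nodes is
    halved.  The final problem minimizes the case-consistent weighted
    objective once; the selected nodes keep their directional sink, every
    other sink is removed from the model.
    """
    if result.n_iterations < 1:
        raise SolverError("finalize_relaxation needs tallies from >= 1 iteration")
    umodel = problem.umodel
    model_real = umodel.model
    freq = result.frequencies
    costs = {}
    for met_id in problem.unmeasured:
        c = 1.0 - freq.get(met_id, 0.0) + FINAL_EPS
        if problem.exo_preference:
            met = model_real.metabolites.get_by_id(met_id)
            if met.compartment == problem.extracellular_compartment:
                c *= 0.5
        costs[met_id] = c

    if problem.m == 0:
        result.final = {}
        return result

    if problem.case in (4, 5):
        model = model_real.copy()
        flux = _solve_qp(problem, model, sink_weights=costs)
        if flux is None:
            raise SolverError("OSQP failed on the final weighted relaxation")
        final = _qp_support(problem, flux)
    else:
        model = model_real.copy()
        machine = _MilpMachine(problem, model)
        iface = model.problem
        if problem.case == 1:
            expr = sum(costs[m] * machine.y[m] for m in problem.unmeasured)
        else:
            expr = sum(
                costs[met_id] * model.reactions.get_by_id(sid).flux_expression
                for met_id in problem.unmeasured
                for sid in problem.umodel.relaxation_sinks[met_id][:2]
            ) + LP_BINARY_EPS * sum(machine.y.values())
            if problem.case == 3:
                expr = expr + sum(_abs_flux_terms(problem, model))
        model.objective = iface.Objective(expr, direction="min")
        model.slim_optimize()
        if model.solver.status != "optimal":
            raise SolverError(
                "final weighted relaxation infeasible (solver-tolerance fault): "
                f"status {model.solver.status!r}"
            )
        if problem.case == 1:
            final = machine.support()
        else:
            final = {}
            for met_id in problem.unmeasured:
                up_id, down_id = umodel.relaxation_sinks[met_id][:2]
                up = model.reactions.get_by_id(up_id).flux
                down = model.reactions.get_by_id(down_id).flux
                if up + down > 1e-6:
                    final[met_id] = "up" if up >= down else "down"

    # prune: retained nodes keep their directional sink, all else removed
    to_remove = []
    new_sinks = {}
    for met_id in problem.unmeasured:
        up_id, down_id = umodel.relaxation_sinks[met_id][:2]
        if met_id in final:
            keep = up_id if final[met_id] == "up" else down_id
            drop = down_id if final[met_id] == "up" else up_id
            to_remove.append(drop)
            new_sinks[met_id] = [keep]
        else:
            to_remove.extend([up_id, down_id])
    model_real.remove_reactions(
        [model_real.reactions.get_by_id(r) for r in to_remove], remove_orphans=False
    )
    umodel.relaxation_sinks = new_sinks
    result.final = final
    return result


def fix_relaxation_magnitudes(
    umodel: UnsteadyModel,
    result: RelaxationResult | None = None,
    scale: float = 1.5,
) -> UnsteadyModel:
    """Minimize total retained-sink flux, then cap each sink at
    ``scale`` × its minimal flux.

    A scale of 1 keeps the model feasible but maximally tight; 1.5 is the
    default working margin.  Sinks whose minimal flux is numerically zero
    are dropped entirely.  Raises :class:`DataError` for ``scale`` < 1.
    """
    if scale < 1:
        raise DataError(f"scale must be >= 1, got {scale}")
    model = umodel.model
    sink_ids = [sid for sids in umodel.relaxation_sinks.values() for sid in sids]
    d_star: dict[str, float] = {}
    if sink_ids:
        with model:
            model.objective = model.problem.Objective(
                sum(model.reactions.get_by_id(s).flux_expression for s in sink_ids),
                direction="min",
            )
            model.slim_optimize()
            if model.solver.status != "optimal":
                raise SolverError(
                    f"sink-minimization LP failed: status {model.solver.status!r}"
                )
            for sid in sink_ids:
                d_star[sid] = float(model.reactions.get_by_id(sid).flux)
    scaled: dict[str, list[float]] = {}
    drop = []
    for met_id, sids in list(umodel.relaxation_sinks.items()):
        for sid in sids:
            d = max(d_star.get(sid, 0.0), 0.0)
            if d <= RELAX_TOL:
                drop.append((met_id, sid))
                continue
            model.reactions.get_by_id(sid).bounds = (0.0, scale * d)
            scaled[met_id] = [0.0, scale * d]
    for met_id, sid in drop:
        model.remove_reactions([model.reactions.get_by_id(sid)], remove_orphans=False)
        umodel.relaxation_sinks[met_id].remove(sid)
        if not umodel.relaxation_sinks[met_id]:
            del umodel.relaxation_sinks[met_id]
    if result is not None:
        result.d_star = {
            met_id: max(d_star.get(sids[0], 0.0), 0.0)
            for met_id, sids in umodel.relaxation_sinks.items()
        }
        result.scaled_bounds = scaled
        result.final = {
            m: d for m, d in result.final.items() if m in umodel.relaxation_sinks
        }
    # the scaled model must remain solvable
    with model:
        model.objective = model.problem.Objective(0)
        model.slim_optimize()
        if model.solver.status != "optimal":
            raise SolverError("model infeasible after scaling relaxation bounds")
    return umodel


def relax(
    umodel: UnsteadyModel,
    case: int = 1,
    iterations: int = 100,
    gap_tol: float = 1e-6,
    time_limit: float = 45.0,
    exo_preference: bool = False,
    extracellular_compartment: str = "e",
    scale: float = 1.5,
    big_m: float = DEFAULT_BOUND,
    seed: int = 0,
) -> tuple[UnsteadyModel, RelaxationResult]:
    """Full relaxation workflow: add sinks, enumerate optima, finalize,
    and fix magnitudes.  Mutates and returns ``umodel`` together with the
    :class:`RelaxationResult` report."""
    problem = add_relaxation_sinks(
        umodel,
        case=case,
        iterations=iterations,
        gap_tol=gap_tol,
        time_limit=time_limit,
        exo_preference=exo_preference,
        extracellular_compartment=extracellular_compartment,
        big_m=big_m,
        seed=seed,
    )
    result = solve_relaxation(problem)
    result = finalize_relaxation(problem, result)
    fix_relaxation_magnitudes(umodel, result, scale=scale)
    return umodel, result
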