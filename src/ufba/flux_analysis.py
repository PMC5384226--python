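"""Interrogation of built models: FBA, FVA, flux sampling, comparison
statistics, internal-loop detection and gene essentiality.

Sampling uses artificial-centering hit-and-run (ACHR) over the flux
polytope; convergence is judged by the *mixed fraction* — the fraction of
(sample, reaction) pairs lying on the same side of the per-reaction median
in the first and second half of the chain (1 when unmixed, 0.5 at full
mixing); the chain is extended with doubled thinning until the diagnostic
drops below 0.54.

uFBA and FBA flux states are compared per reaction by the overlap
coefficient of the two empirical flux distributions on a shared binning
(significantly different iff overlap < 5%) and globally by the
distribution of Spearman correlations of randomly paired sample vectors.
Reactions that can carry flux with every boundary reaction closed
(internal, thermodynamically infeasible "type 3" loops) are excluded from
both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import cobra
from scipy.linalg import null_space
from scipy.optimize import linprog

from ufba.errors import DataError, SolverError
from ufba.model_core import DEFAULT_BOUND, stoichiometric_matrix
from ufba.ufba_build import UnsteadyModel

FEASIBILITY_TOL = 1e-6


def _as_model(model) -> cobra.Model:
    return model.model if isinstance(model, UnsteadyModel) else model


@dataclass
class FluxResult:
    """Outcome of a single LP solve; ``status`` is "optimal" or the solver
    status string (e.g. "infeasible") — infeasibility is a result, not an
    exception."""

    status: str
    objective_value: float | None
    fluxes: pd.Series | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxSampleSet:
    """Feasible flux vectors (samples × reactions) with convergence
    diagnostics."""

    samples: pd.DataFrame
    mixed_fraction: float
    threshold: float
    n_samples: int
    seed: int
    thinning: int

    @property
    def converged(self) -> bool:
        return self.mixed_fraction <= self.threshold

    @property
    def reactions(self) -> list[str]:
        return list(self.samples.columns)


@dataclass
class FluxComparison:
    """Per-reaction overlap of two sampled flux states plus the Spearman
    correlation distribution over paired sample vectors."""

    overlap: pd.Series
    significant: pd.Series
    spearman: np.ndarray
    reactions: list = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def optimize(model, objective_reaction: str | None = None, sense: str = "max") -> FluxResult:
    """Solve the FBA LP for ``objective_reaction`` (or the model's own
    objective when omitted)."""
    m = _as_model(model)
    with m:
        if objective_reaction is not None:
            m.objective = m.reactions.get_by_id(objective_reaction)
        m.objective_direction = "max" if sense == "max" else "min"
        sol = m.optimize()
        if sol.status != "optimal":
            return FluxResult(status=sol.status, objective_value=None, fluxes=None)
        return FluxResult(status="optimal", objective_value=float(sol.objective_value),
                          fluxes=sol.fluxes.copy())


def fva(model, reactions: list | None = None) -> pd.DataFrame:
    """Per-reaction flux variability over the full feasible set.

    Returns a DataFrame indexed by reaction id with columns
    ``minimum, maximum, range`` (range = maximum − minimum ≥ 0).
    """
    m = _as_model(model)
    from cobra.flux_analysis import flux_variability_analysis

    with m:
        m.objective = m.problem.Objective(0)
        try:
            df = flux_variability_analysis(
                m, reaction_list=reactions, fraction_of_optimum=0.0, processes=1
            )
        except Exception as exc:
            raise SolverError(f"FVA failed (model infeasible?): {exc}") from exc
    df = df.copy()
    df["range"] = (df["maximum"] - df["minimum"]).clip(lower=0.0)
    return df


def _validate_samples(model: cobra.Model, samples: pd.DataFrame, tol: float) -> pd.DataFrame:
    """Keep only samples satisfying S·v = 0 and bounds within ``tol``."""
    S, _, rxn_ids = stoichiometric_matrix(model)
    X = samples[rxn_ids].to_numpy()
    lb = np.array([model.reactions.get_by_id(r).lower_bound for r in rxn_ids])
    ub = np.array([model.reactions.get_by_id(r).upper_bound for r in rxn_ids])
    mass_ok = np.abs(S @ X.T).max(axis=0) <= tol
    bound_ok = ((X >= lb - tol) & (X <= ub + tol)).all(axis=1)
    return samples[mass_ok & bound_ok]


def mixed_fraction(samples: np.ndarray) -> float:
    """Convergence diagnostic of an ordered chain of samples.

    Per reaction, pair sample i of the first half with sample i of the
    second half and count pairs on the same side of the full-chain median;
    the average over reactions is 1 for a frozen chain and 0.5 for a fully
    mixed one.  Reactions with (numerically) constant flux are skipped.
    """
    X = np.asarray(samples, dtype=float)
    n = X.shape[0] // 2
    if n < 1:
        return 1.0
    med = np.median(X, axis=0)
    spread = X.max(axis=0) - X.min(axis=0)
    active = spread > 1e-9
    if not active.any():
        return 0.5
    first = X[:n, active] > med[active]
    second = X[n : 2 * n, active] > med[active]
    return float((first == second).mean())


def sample_fluxes(
    model,
    n_samples: int = 1000,
    seed: int = 0,
    mixed_fraction_threshold: float = 0.54,
    initial_thinning: int = 100,
    max_rounds: int = 4,
    validate_tol: float = FEASIBILITY_TOL,
) -> FluxSampleSet:
    """ACHR sampling of the flux polytope until the mixed fraction falls
    below the convergence threshold (thinning doubles each round).

    Every returned sample is validated against the model's constraints at
    ``validate_tol``; the polytope must be bounded (finite bounds on every
    reaction).  A fully determined polytope (all FVA ranges ~0) returns
    ``n_samples`` copies of the unique point.
    """
    m = _as_model(model)
    for rxn in m.reactions:
        if not np.isfinite(rxn.lower_bound) or not np.isfinite(rxn.upper_bound):
            raise DataError(
                f"reaction {rxn.id!r} has an infinite bound; close the polytope "
                "before sampling"
            )
    S, _, rxn_ids = stoichiometric_matrix(m)
    lb = np.array([m.reactions.get_by_id(r).lower_bound for r in rxn_ids])
    ub = np.array([m.reactions.get_by_id(r).upper_bound for r in rxn_ids])
    thinning = initial_thinning
    best = None
    for _ in range(max_rounds):
        X = _achr_chain(S, lb, ub, n_samples, thinning, seed)
        mf = mixed_fraction(X)
        if best is None or mf < best[0]:
            best = (mf, X, thinning)
        if mf <= mixed_fraction_threshold:
            break
        thinning *= 2
    mf, X, thinning = best
    samples = pd.DataFrame(X, columns=rxn_ids)
    samples = _validate_samples(m, samples, validate_tol).reset_index(drop=True)
    return FluxSampleSet(
        samples=samples, mixed_fraction=mf, threshold=mixed_fraction_threshold,
        n_samples=len(samples), seed=seed, thinning=thinning,
    )


def _achr_chain(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    n_samples: int,
    thinning: int,
    seed: int,
) -> np.ndarray:
    """Artificial-centering hit-and-run over {v : S·v = 0, lb <= v <= ub}.

    The walk runs in null-space coordinates (so the mass balances hold to
    machine precision), warm-started from the FVA vertices; each step picks
    the chord through the current point along a direction from a randomly
    chosen earlier point to the running centre, and jumps uniformly on it.
    """
    rng = np.random.default_rng(seed)
    n = S.shape[1]
    N = null_space(S) if S.size else np.eye(n)
    # warmup: FVA vertices (min and max of each coordinate)
    warm = []
    v0 = None
    for j in range(n):
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(c, A_eq=S if S.size else None, b_eq=np.zeros(S.shape[0]) if S.size else None,
                          bounds=list(zip(lb, ub)), method="highs")
            if res.status == 0:
                warm.append(res.x)
                v0 = res.x if v0 is None else v0
    if v0 is None:
        raise SolverError("flux polytope is empty; nothing to sample")
    if N.shape[1] == 0:
        return np.tile(v0, (n_samples, 1))
    W = np.array(warm)
    A = (W - v0) @ N  # warmup points in null-space coordinates
    spans = A.max(axis=0) - A.min(axis=0)
    if np.all(spans < 1e-10):
        return np.tile(v0, (n_samples, 1))
    pool = [a for a in A]
    center = A.mean(axis=0)
    cur = center.copy()
    out = np.empty((n_samples, n))
    eps = 1e-12
    produced = 0
    step = 0
    max_steps = (n_samples * thinning) * 20 + 1000
    while produced < n_samples and step < max_steps:
        step += 1
        ref = pool[rng.integers(len(pool))]
        d = ref - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            d = rng.standard_normal(len(cur))
            norm = np.linalg.norm(d)
        d /= norm
        dv = N @ d
        v = v0 + N @ cur
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (lb - v) / dv
            hi = (ub - v) / dv
        active = np.abs(dv) > 1e-11
        if not active.any():
            continue
        tmin = np.maximum(np.where(dv > 0, lo, hi)[active], -1e12).max()
        tmax = np.minimum(np.where(dv > 0, hi, lo)[active], 1e12).min()
        if tmax - tmin < eps:
            continue
        t = rng.uniform(tmin, tmax)
        nxt = cur + t * d
        center = center + (nxt - center) / (len(pool) + 1)
        pool.append(nxt)
        cur = nxt
        if step % thinning == 0:
            out[produced] = v0 + N @ cur
            produced += 1
    if produced < n_samples:
        out = out[:produced]
    return out


def exclude_loop_reactions(model, tol: float = FEASIBILITY_TOL) -> set[str]:
    """Reactions able to carry flux with every boundary reaction closed.

    All single-metabolite (exchange/accumulation/sink) reactions are fixed
    to zero and FVA is run; any reaction whose flux range then escapes
    ±``tol`` is a member of an internal (type 3) loop.
    """
    m = _as_model(model).copy()
    for rxn in m.reactions:
        if len(rxn.metabolites) == 1:
            rxn.bounds = (0.0, 0.0)
    df = fva(m)
    return {
        rid
        for rid in df.index
        if df.loc[rid, "maximum"] > tol or df.loc[rid, "minimum"] < -tol
    }


def _overlap_coefficient(x: np.ndarray, y: np.ndarray, min_bins: int = 20) -> float:
    """Overlap of two empirical distributions on a shared equal-width
    binning (Freedman–Diaconis on the pooled sample, floored at
    ``min_bins`` bins)."""
    pooled = np.concatenate([x, y])
    lo, hi = pooled.min(), pooled.max()
    if hi - lo < 1e-12:
        return 1.0
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    fd = 2 * iqr / len(pooled) ** (1 / 3) if iqr > 0 else 0.0
    n_bins = int(np.ceil((hi - lo) / fd)) if fd > 0 else min_bins
    n_bins = int(np.clip(n_bins, min_bins, 200))
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(x, bins=edges)
    q, _ = np.histogram(y, bins=edges)
    return float(np.minimum(p / len(x), q / len(y)).sum())


def compare_flux_states(
    a: FluxSampleSet,
    b: FluxSampleSet,
    model_a=None,
    model_b=None,
    overlap_threshold: float = 0.05,
    seed: int = 0,
) -> FluxComparison:
    """Contrast two sampled flux states (typically uFBA vs FBA).

    The comparison is restricted to reactions present in both sample sets
    and not involved in internal loops of either model.  Per reaction the
    overlap coefficient of the two flux distributions is computed
    (significantly different iff < ``overlap_threshold``); globally, both
    sample sets are shuffled once (seeded) and sample i of A is paired
    with sample i of B, yielding one Spearman correlation per stored pair.
    """
    shared = sorted(set(a.reactions) & set(b.reactions))
    loops = set()
    if model_a is not None:
        loops |= exclude_loop_reactions(model_a)
    if model_b is not None:
        loops |= exclude_loop_reactions(model_b)
    shared = [r for r in shared if r not in loops]
    if not shared:
        raise DataError("no shared (loop-free) reactions to compare")
    A = a.samples[shared].to_numpy()
    B = b.samples[shared].to_numpy()
    overlap = pd.Series(
        [_overlap_coefficient(A[:, j], B[:, j]) for j in range(len(shared))],
        index=shared,
    )
    significant = overlap < overlap_threshold
    rng = np.random.default_rng(seed)
    n = min(len(A), len(B))
    ia = rng.permutation(len(A))[:n]
    ib = rng.permutation(len(B))[:n]
    cors = []
    for i in range(n):
        va, vb = A[ia[i]], B[ib[i]]
        if np.ptp(va) < 1e-12 or np.ptp(vb) < 1e-12:
            continue
        rho = stats.spearmanr(va, vb).statistic
        if np.isfinite(rho):
            cors.append(rho)
    return FluxComparison(
        overlap=overlap,
        significant=significant,
        spearman=np.asarray(cors),
        reactions=shared,
    )


def _prepare_essentiality_model(umodel: UnsteadyModel, extracellular_compartment: str = "e") -> cobra.Model:
    """Make the zero flux vector feasible and open efflux, as growth
    screening on an unsteady model requires.

    Any bound pair excluding zero (forced accumulation/depletion) is
    widened to include it, and every extracellular metabolite without a
    boundary reaction receives a secretion-only efflux.
    """
    m = umodel.model.copy()
    for rxn in m.reactions:
        lb, ub = rxn.bounds
        if lb > 0:
            lb = 0.0
        if ub < 0:
            ub = 0.0
        rxn.bounds = (lb, ub)
    have_boundary = {
        met.id for rxn in m.reactions if len(rxn.metabolites) == 1 for met in rxn.metabolites
    }
    new = []
    for met in m.metabolites:
        if met.compartment == extracellular_compartment and met.id not in have_boundary:
            rxn = cobra.Reaction("ESSEFFLUX_" + met.id, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
            rxn.add_metabolites({met: -1.0})
            new.append(rxn)
    m.add_reactions(new)
    return m


def gene_essentiality(
    model,
    growth_reaction: str,
    reference_growth: float,
    threshold_fraction: float = 0.01,
    extracellular_compartment: str = "e",
) -> pd.Series:
    """Single-gene knockout screen.

    Each gene is set false in every gene rule, reactions whose rule
    evaluates false are disabled, and growth is re-maximized; a gene is
    essential iff the knockout optimum falls below
    ``threshold_fraction × reference_growth``.  For an
    :class:`UnsteadyModel` the screen runs on a copy in which constraints
    conflicting with the zero vector are relaxed and extracellular efflux
    is opened, so that "no growth" is expressible.

    Returns a boolean Series indexed by gene id (True = essential).
    """
    if reference_growth <= 0:
        raise DataError("reference growth must be positive")
    if isinstance(model, UnsteadyModel):
        m = _prepare_essentiality_model(model, extracellular_compartment)
    else:
        m = _as_model(model).copy()
    if growth_reaction not in {r.id for r in m.reactions}:
        raise DataError(f"growth reaction {growth_reaction!r} not in model")
    threshold = threshold_fraction * reference_growth
    out = {}
    for gene in m.genes:
        with m:
            gene.knock_out()
            m.objective = m.reactions.get_by_id(growth_reaction)
            m.objective_direction = "max"
            value = m.slim_optimize(error_value=0.0)
        if value is None or not np.isfinite(value):
            value = 0.0
        out[gene.id] = bool(value < threshold)
    return pd.Series(out, dtype=bool).sort_index()
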