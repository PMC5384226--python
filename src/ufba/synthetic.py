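"""Synthetic fixtures: toy metabolic networks and ground-truth time courses.

The generator emulates the statistical structure the workflow assumes:
piecewise-linear concentration trajectories C(t) = C0 + (S·v_state)·t per
metabolic state, multiplicative replicate noise, missing values, and
incomplete metabolite coverage.  Five documented topologies cover the
scientifically interesting motifs:

``chain``
    Linear pathway with uptake and secretion exchanges.
``branched``
    A split/merge diamond between two exchanges.
``pool_depletion``
    A large intracellular pool (malate-like) feeding a secreted product
    through a reversible dehydrogenase; with the pool measurement the
    dehydrogenase runs pool → network, without it the steady-state control
    predicts the opposite direction — the flux-reversal motif.
``cofactor_rescue``
    Growth consumes a cofactor that can be synthesized (gene ``gBio``) or
    drawn from a measured depleting pool; knockout of ``gBio`` is lethal
    under the steady-state control but rescued by the pool under the
    unsteady model — the cofactor-rescue essentiality motif.
``twin_pathway``
    Two symmetric routes out of one measured depleting pool; the node
    relaxation problem has exactly two alternative optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import cobra

from ufba.errors import DataError
from ufba.model_core import DEFAULT_BOUND, stoichiometric_matrix
from ufba.timecourse import RateEstimate, TimeCourseDataset


def _met(mid: str, compartment: str) -> cobra.Metabolite:
    m = cobra.Metabolite(mid, compartment=compartment)
    return m


def _rxn(model: cobra.Model, rid: str, stoich: dict, lb: float, ub: float,
         gene_rule: str = "", objective: float = 0.0) -> cobra.Reaction:
    r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
    r.add_metabolites({model.metabolites.get_by_id(k): v for k, v in stoich.items()})
    if gene_rule:
        r.gene_reaction_rule = gene_rule
    model.add_reactions([r])
    if objective:
        r.objective_coefficient = objective
    return r


def make_toy_network(kind: str, size: int = 3, reversible: bool = False, seed: int = 0) -> cobra.Model:
    """Construct one of the documented toy topologies.

    ``size`` only applies to ``chain`` (number of internal reactions,
    2–10).  ``reversible`` makes chain/branched internal reactions
    reversible.  Raises :class:`DataError` for an unknown kind.
    """
    lbi = -DEFAULT_BOUND if reversible else 0.0
    if kind == "chain":
        if not 2 <= size <= 10:
            raise DataError("chain size must be in 2..10")
        model = cobra.Model("chain")
        model.add_metabolites(
            [_met("m0", "e")]
            + [_met(f"m{i}", "c") for i in range(1, size)]
            + [_met(f"m{size}", "e")]
        )
        for i in range(1, size + 1):
            _rxn(model, f"R{i}", {f"m{i-1}": -1, f"m{i}": 1}, lbi, DEFAULT_BOUND)
        _rxn(model, "EX_m0", {"m0": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, f"EX_m{size}", {f"m{size}": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        return model
    if kind == "branched":
        model = cobra.Model("branched")
        model.add_metabolites(
            [_met("s_e", "e"), _met("a_c", "c"), _met("b_c", "c"),
             _met("c_c", "c"), _met("d_c", "c"), _met("p_e", "e")]
        )
        _rxn(model, "T_in", {"s_e": -1, "a_c": 1}, lbi, DEFAULT_BOUND)
        _rxn(model, "B1", {"a_c": -1, "b_c": 1}, lbi, DEFAULT_BOUND)
        _rxn(model, "B2", {"a_c": -1, "c_c": 1}, lbi, DEFAULT_BOUND)
        _rxn(model, "MERGE", {"b_c": -1, "c_c": -1, "d_c": 2}, lbi, DEFAULT_BOUND)
        _rxn(model, "T_out", {"d_c": -1, "p_e": 1}, lbi, DEFAULT_BOUND)
        _rxn(model, "EX_s", {"s_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_p", {"p_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        return model
    if kind == "pool_depletion":
        model = cobra.Model("pool_depletion")
        model.add_metabolites(
            [_met("cit_e", "e"), _met("cit_c", "c"), _met("oaa_c", "c"),
             _met("mal_c", "c"), _met("mal_e", "e"), _met("asp_e", "e"),
             _met("pyr_c", "c"), _met("lac_c", "c"), _met("lac_e", "e")]
        )
        _rxn(model, "CITt", {"cit_e": -1, "cit_c": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "CITL", {"cit_c": -1, "oaa_c": 1}, 0, DEFAULT_BOUND)
        # reversible dehydrogenase between the pool and the backbone
        _rxn(model, "MDH", {"oaa_c": -1, "mal_c": 1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "MALt", {"mal_c": -1, "mal_e": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "OAADC", {"oaa_c": -1, "pyr_c": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "ASPt", {"oaa_c": -1, "asp_e": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "LDH", {"pyr_c": -1, "lac_c": 1}, 0, DEFAULT_BOUND)
        # capacity-limited overflow yielding two product units per substrate:
        # its activity consumes spare disposal capacity, so it shuts down
        # whenever the downstream sink is pinned at its minimum
        _rxn(model, "BYP", {"pyr_c": -1, "lac_c": 2}, 0, 0.6)
        _rxn(model, "LACt", {"lac_c": -1, "lac_e": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "EX_cit", {"cit_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_mal", {"mal_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_asp", {"asp_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_lac", {"lac_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        return model
    if kind == "cofactor_rescue":
        model = cobra.Model("cofactor_rescue")
        model.add_metabolites(
            [_met("glc_e", "e"), _met("glc_c", "c"), _met("nad_c", "c"), _met("ac_e", "e")]
        )
        _rxn(model, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, DEFAULT_BOUND, gene_rule="gT")
        _rxn(model, "NADS", {"glc_c": -1, "nad_c": 1}, 0, DEFAULT_BOUND, gene_rule="gBio")
        _rxn(model, "OVERFLOW", {"glc_c": -1, "ac_e": 1}, 0, DEFAULT_BOUND, gene_rule="gOvf")
        _rxn(model, "GROWTH", {"glc_c": -1, "nad_c": -0.2}, 0, DEFAULT_BOUND, objective=1.0)
        _rxn(model, "EX_glc", {"glc_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_ac", {"ac_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        return model
    if kind == "twin_pathway":
        model = cobra.Model("twin_pathway")
        model.add_metabolites([_met("a_c", "c"), _met("x1_c", "c"), _met("x2_c", "c")])
        _rxn(model, "R1", {"a_c": -1, "x1_c": 1}, 0, DEFAULT_BOUND)
        _rxn(model, "R2", {"a_c": -1, "x2_c": 1}, 0, DEFAULT_BOUND)
        return model
    raise DataError(f"unknown toy-network kind {kind!r}")


@dataclass
class SyntheticScenario:
    """A toy network with known flux states and simulation parameters.

    ``state_fluxes`` gives one flux vector (reaction id → flux, in the
    open model with exchanges) per metabolic state; ``state_times`` the
    sampling times per state (hours, globally increasing).  ``measured``
    lists the metabolite ids included in the generated dataset (incomplete
    coverage is the default condition the workflow must cope with).
    """

    model: cobra.Model
    state_fluxes: list
    state_times: list
    initial_concentrations: dict
    measured: list
    replicates: int = 5
    noise_sd: float = 0.05
    missing_fraction: float = 0.0
    seed: int = 0
    units: str = "mmol/L"
    growth_reaction: str | None = None
    reference_growth: float | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DataError("noise SD must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise DataError("missing fraction must be in [0, 1)")
        for v in self.state_fluxes:
            for rid, flux in v.items():
                rxn = self.model.reactions.get_by_id(rid)
                if not (rxn.lower_bound - 1e-9 <= flux <= rxn.upper_bound + 1e-9):
                    raise DataError(f"true flux for {rid} violates its bounds")

    def true_rates(self) -> list:
        """Per state, the exact rate of change b = S·v for every metabolite.

        Exchange (single-metabolite boundary) columns are excluded: the
        exchange flux moves material across the system boundary, and the
        pool it drains or feeds is exactly the extracellular concentration
        whose change b describes.
        """
        S, met_ids, rxn_ids = stoichiometric_matrix(self.model)
        internal = np.array(
            [len(self.model.reactions.get_by_id(r).metabolites) > 1 for r in rxn_ids]
        )
        out = []
        for vdict in self.state_fluxes:
            v = np.array([vdict.get(r, 0.0) for r in rxn_ids]) * internal
            b = S @ v
            out.append({m: float(x) for m, x in zip(met_ids, b)})
        return out

    def state_boundaries(self) -> list:
        return [float(ts[0]) for ts in self.state_times[1:]]


def make_scenario(kind: str, seed: int = 0, noise_sd: float = 0.05,
                  replicates: int = 5, missing_fraction: float = 0.0,
                  pool_measured: bool = True) -> SyntheticScenario:
    """Canonical study conditions for each motif.

    Defaults mirror the structure of a well-replicated storage/fermentation
    time course: 10 time points per state, 5 replicates, 5% relative noise.
    """
    ten = np.arange(10, dtype=float)
    if kind == "pool_depletion":
        model = make_toy_network("pool_depletion")
        flux = {
            "CITt": 1.0, "CITL": 1.0, "MDH": -1.5, "MALt": 0.5,
            "OAADC": 2.35, "ASPt": 0.15, "LDH": 2.05, "BYP": 0.3, "LACt": 2.65,
            "EX_cit": -1.0, "EX_mal": 0.5, "EX_asp": 0.15, "EX_lac": 2.65,
        }
        c0 = {"cit_e": 15.0, "cit_c": 2.0, "oaa_c": 1.0, "mal_c": 25.0,
              "mal_e": 1.0, "asp_e": 2.0, "pyr_c": 2.0, "lac_c": 2.0, "lac_e": 1.0}
        measured = ["cit_e", "mal_c", "mal_e", "asp_e"]
        return SyntheticScenario(
            model=model, state_fluxes=[flux], state_times=[ten],
            initial_concentrations=c0, measured=measured, replicates=replicates,
            noise_sd=noise_sd, missing_fraction=missing_fraction, seed=seed,
        )
    if kind == "cofactor_rescue":
        model = make_toy_network("cofactor_rescue")
        flux = {
            "GLCt": 2.0, "NADS": 0.25, "OVERFLOW": 0.0, "GROWTH": 1.75,
            "EX_glc": -2.0, "EX_ac": 0.0,
        }
        c0 = {"glc_e": 25.0, "glc_c": 2.0, "nad_c": 2.0, "ac_e": 0.5}
        measured = ["glc_e", "nad_c"] if pool_measured else ["glc_e"]
        return SyntheticScenario(
            model=model, state_fluxes=[flux], state_times=[ten],
            initial_concentrations=c0, measured=measured, replicates=replicates,
            noise_sd=noise_sd, missing_fraction=missing_fraction, seed=seed,
            growth_reaction="GROWTH", reference_growth=1.75,
        )
    if kind == "twin_pathway":
        model = make_toy_network("twin_pathway")
        # a depleting pool split equally between the twin routes
        flux = {"R1": 0.5, "R2": 0.5}
        c0 = {"a_c": 15.0, "x1_c": 1.0, "x2_c": 1.0}
        return SyntheticScenario(
            model=model, state_fluxes=[flux], state_times=[ten],
            initial_concentrations=c0, measured=["a_c"], replicates=replicates,
            noise_sd=noise_sd, missing_fraction=missing_fraction, seed=seed,
        )
    if kind == "negative_control":
        # balanced growth-like condition: only extracellular metabolites
        # change, all interior nodes stay at steady state, so the unsteady
        # model and its control describe the same feasible set
        model = make_toy_network("branched")
        flux = {"T_in": 1.0, "B1": 0.5, "B2": 0.5, "MERGE": 0.5, "T_out": 1.0,
                "EX_s": -1.0, "EX_p": 1.0}
        c0 = {"s_e": 15.0, "a_c": 2.0, "b_c": 2.0, "c_c": 2.0, "d_c": 2.0, "p_e": 1.0}
        return SyntheticScenario(
            model=model, state_fluxes=[flux], state_times=[ten],
            initial_concentrations=c0, measured=["s_e", "p_e"], replicates=replicates,
            noise_sd=noise_sd, missing_fraction=missing_fraction, seed=seed,
        )
    if kind == "chain_two_state":
        model = make_toy_network("chain", size=3, reversible=True)
        fwd = {"R1": 1.0, "R2": 1.0, "R3": 1.0, "EX_m0": -1.0, "EX_m3": 1.0}
        rev = {k: -v for k, v in fwd.items()}
        c0 = {"m0": 15.0, "m1": 3.0, "m2": 3.0, "m3": 2.0}
        return SyntheticScenario(
            model=model, state_fluxes=[fwd, rev],
            state_times=[ten, ten + 10.0],
            initial_concentrations=c0, measured=["m0", "m1", "m2", "m3"],
            replicates=replicates, noise_sd=noise_sd,
            missing_fraction=missing_fraction, seed=seed,
        )
    raise DataError(f"unknown scenario kind {kind!r}")


def simulate_timecourse(scenario: SyntheticScenario):
    """Generate a noisy time-course dataset plus its ground truth.

    Noiseless trajectories are piecewise linear per state
    (C = C0 + b·Δt, b = S·v_state, accumulated across states); replicate
    noise is multiplicative Gaussian with relative SD ``noise_sd``;
    missingness is applied uniformly at ``missing_fraction``; finally only
    ``measured`` metabolites are kept.  Identical seeds yield identical
    datasets bit for bit.

    Returns ``(TimeCourseDataset, truth)`` where ``truth`` holds the per
    state rates, the state boundaries, the true flux vectors and the
    measured-metabolite list.
    """
    rng = np.random.default_rng(scenario.seed)
    rates = scenario.true_rates()
    met_ids = [m.id for m in scenario.model.metabolites]
    conc = {m: scenario.initial_concentrations.get(m, 10.0) for m in met_ids}
    rows = []
    state_start_conc = dict(conc)
    for s, (vdict, times) in enumerate(zip(scenario.state_fluxes, scenario.state_times)):
        t0 = times[0]
        for t in times:
            for m in met_ids:
                clean = state_start_conc[m] + rates[s][m] * (t - t0)
                if clean < -1e-9:
                    raise DataError(
                        f"scenario drives {m} negative at t={t}; raise its C0"
                    )
                for rep in range(scenario.replicates):
                    noisy = clean * (1.0 + scenario.noise_sd * rng.standard_normal())
                    rows.append((m, scenario.model.metabolites.get_by_id(m).compartment,
                                 float(t), rep, max(noisy, 0.0)))
        # the next state continues from this state's final concentration
        t_end = times[-1]
        for m in met_ids:
            state_start_conc[m] = state_start_conc[m] + rates[s][m] * (t_end - t0)

    df = pd.DataFrame(rows, columns=["metabolite_id", "compartment", "time",
                                     "replicate", "concentration"])
    if scenario.missing_fraction > 0:
        mask = rng.random(len(df)) < scenario.missing_fraction
        # never blank out an entire metabolite profile
        for m in met_ids:
            rows_m = df.index[df["metabolite_id"] == m]
            if mask[rows_m].all():
                mask[rows_m[0]] = False
        df.loc[mask, "concentration"] = np.nan
    df = df[df["metabolite_id"].isin(scenario.measured)].reset_index(drop=True)
    data = TimeCourseDataset(data=df, units=scenario.units)
    truth = {
        "rates": rates,
        "state_boundaries": scenario.state_boundaries(),
        "fluxes": scenario.state_fluxes,
        "measured": list(scenario.measured),
    }
    return data, truth


def make_random_instance(seed: int, max_metabolites: int = 13,
                         max_reactions: int = 20,
                         max_unmeasured: int = 12,
                         interval_halfwidth: float = 0.05):
    """A random irreversible network with measured-rate intervals.

    The network is built around a random strictly positive flux vector:
    every reaction moves material from one or two substrates to one or two
    products, so S·v* defines a consistent set of per-metabolite rates.  A
    random subset of metabolites is "measured" and receives a rate interval
    [b−h, b+h] centred on the truth; the rest (at most ``max_unmeasured``)
    are unmeasured, so any net production or consumption they carry must be
    absorbed by node relaxation.  Useful as a stress fixture for relaxation
    algorithms because minimal relaxations are known by exhaustive search.

    Returns ``(model, rate_estimates, truth)`` where ``truth`` holds the
    flux vector and exact rates.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(5, max_metabolites + 1))
    n_rxns = int(rng.integers(n_mets, max_reactions + 1))
    model = cobra.Model(f"random_{seed}")
    met_ids = [f"m{i}" for i in range(n_mets)]
    model.add_metabolites([_met(m, "c") for m in met_ids])
    for j in range(n_rxns):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(n_mets, size=n_sub + n_prod, replace=False)
        stoich = {}
        for m in picks[:n_sub]:
            stoich[met_ids[m]] = -1.0
        for m in picks[n_sub:]:
            stoich[met_ids[m]] = 1.0
        _rxn(model, f"R{j}", stoich, 0.0, DEFAULT_BOUND)
    v_true = rng.uniform(0.2, 3.0, size=n_rxns)
    S, s_mets, s_rxns = stoichiometric_matrix(model)
    v = np.array([v_true[int(r[1:])] for r in s_rxns])
    b = dict(zip(s_mets, S @ v))
    n_measured = max(n_mets - max_unmeasured, int(round(0.4 * n_mets)))
    measured = sorted(rng.choice(met_ids, size=n_measured, replace=False))
    h = interval_halfwidth
    rates = []
    for m in measured:
        bm = float(b[m])
        rates.append(RateEstimate(
            metabolite_id=m, state_index=0, slope=bm, b1=bm - h, b2=bm + h,
            significant=not (bm - h <= 0.0 <= bm + h), compartment="c",
        ))
    truth = {"fluxes": {r: float(x) for r, x in zip(s_rxns, v)},
             "rates": {m: float(x) for m, x in b.items()},
             "measured": measured}
    return model, rates, truth
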