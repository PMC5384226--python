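"""Build unsteady-state (closed-system) models and their FBA controls.

The unsteady mass balance S·v = b, with b inside the measured 95%
confidence interval [b1, b2] per metabolite, is realized by adding a
single-metabolite *accumulation* pseudo-reaction per significantly
changing metabolite: stoichiometry {met: −1}, bounds [b1, b2].  Positive
flux through it drains the network into the measured pool (accumulation);
negative flux feeds the pool back (depletion).  With that column in place
every constraint is in standard S·v = 0 form, so downstream LP/MILP/QP and
sampling machinery needs no special right-hand side.

``build_ufba_model`` closes the system entirely (all exchange reactions
removed) and integrates every significant rate, intracellular and
extracellular alike.  ``build_fba_control`` is the matched steady-state
control: only extracellular rates are integrated, all intracellular
metabolites stay balanced, and every unmeasured extracellular metabolite
receives a free efflux (secretion-only) exchange — the conventional FBA
treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import cobra

from ufba.errors import ModelValidationError, DataError
from ufba.model_core import DEFAULT_BOUND, find_exchange_reactions, read_model, write_model
from ufba.timecourse import RateEstimate

ACC_PREFIX = "ACC_"
RELAX_UP_PREFIX = "RELAX_UP_"
RELAX_DOWN_PREFIX = "RELAX_DOWN_"
EFFLUX_PREFIX = "EFFLUX_"
RESERVE_PREFIX = "RESERVE_"


@dataclass
class UnsteadyModel:
    """A closed-system model carrying unsteady mass-balance bounds.

    ``accumulation`` maps metabolite id → accumulation reaction id;
    ``relaxation_sinks`` maps metabolite id → (up sink id, down sink id)
    once sinks are installed; ``measured`` is the set of metabolite ids
    whose significant rate was integrated.  ``mode`` distinguishes the
    closed uFBA model from its FBA control.
    """

    model: cobra.Model
    accumulation: dict = field(default_factory=dict)
    relaxation_sinks: dict = field(default_factory=dict)
    measured: set = field(default_factory=set)
    free_efflux: dict = field(default_factory=dict)
    reserves: dict = field(default_factory=dict)
    state_index: int | None = None
    mode: str = "ufba"
    growth_bounds: tuple | None = None

    def pseudo_reaction_ids(self) -> set[str]:
        ids = set(self.accumulation.values()) | set(self.free_efflux.values())
        ids |= set(self.reserves.values())
        for sink_ids in self.relaxation_sinks.values():
            ids.update(sink_ids)
        return ids

    def copy(self) -> "UnsteadyModel":
        return UnsteadyModel(
            model=self.model.copy(),
            accumulation=dict(self.accumulation),
            relaxation_sinks=dict(self.relaxation_sinks),
            measured=set(self.measured),
            free_efflux=dict(self.free_efflux),
            reserves=dict(self.reserves),
            state_index=self.state_index,
            mode=self.mode,
            growth_bounds=self.growth_bounds,
        )


def _dedupe(rates: list[RateEstimate]) -> dict[str, RateEstimate]:
    out: dict[str, RateEstimate] = {}
    for r in rates:
        if r.metabolite_id in out:
            raise DataError(
                f"two rate estimates for metabolite {r.metabolite_id!r} in one state"
            )
        out[r.metabolite_id] = r
    return out


def _add_accumulation(model: cobra.Model, met: cobra.Metabolite, b1: float, b2: float) -> str:
    rxn = cobra.Reaction(ACC_PREFIX + met.id, lower_bound=b1, upper_bound=b2)
    rxn.add_metabolites({met: -1.0})
    rxn.annotation["pseudo"] = "accumulation"
    model.add_reactions([rxn])
    return rxn.id


def _apply_growth_bounds(model: cobra.Model, growth_rate) -> tuple | None:
    if growth_rate is None:
        return None
    lo, hi = growth_rate
    biomass = [r for r in model.reactions if r.objective_coefficient]
    if not biomass:
        raise ModelValidationError("growth-rate bounds given but model has no objective reaction")
    for rxn in biomass:
        rxn.bounds = (lo, hi)
    return (lo, hi)


def build_ufba_model(
    model: cobra.Model,
    rates: list[RateEstimate],
    growth_rate: tuple | None = None,
    reserves: tuple = (),
    state_index: int | None = None,
) -> UnsteadyModel:
    """Close the system and integrate measured rates of change.

    All exchange reactions are removed.  Each *significant* rate estimate
    becomes an accumulation reaction with bounds [b1, b2]; non-significant
    and unmeasured metabolites are held at steady state.  Extracellular and
    intracellular metabolites are treated identically.  ``growth_rate``
    (lower, upper) bounds the objective (biomass) reaction when supplied;
    ``reserves`` names metabolites granted an unconditional reversible sink
    (e.g. glycogen stores).
    """
    m = model.copy()
    known = {met.id for met in m.metabolites}
    for r in rates:
        if r.metabolite_id not in known:
            raise DataError(f"rate estimate for unknown metabolite {r.metabolite_id!r}")
    by_met = _dedupe(rates)
    m.remove_reactions(
        [m.reactions.get_by_id(rid) for rid in find_exchange_reactions(m)],
        remove_orphans=False,
    )
    accumulation: dict[str, str] = {}
    for met_id, est in sorted(by_met.items()):
        if not est.significant:
            continue
        accumulation[met_id] = _add_accumulation(m, m.metabolites.get_by_id(met_id), est.b1, est.b2)
    reserve_map: dict[str, str] = {}
    for met_id in reserves:
        rxn = cobra.Reaction(RESERVE_PREFIX + met_id, lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND)
        rxn.add_metabolites({m.metabolites.get_by_id(met_id): -1.0})
        rxn.annotation["pseudo"] = "reserve"
        m.add_reactions([rxn])
        reserve_map[met_id] = rxn.id
    growth_bounds = _apply_growth_bounds(m, growth_rate)
    return UnsteadyModel(
        model=m,
        accumulation=accumulation,
        measured=set(accumulation),
        reserves=reserve_map,
        state_index=state_index,
        mode="ufba",
        growth_bounds=growth_bounds,
    )


def build_fba_control(
    model: cobra.Model,
    rates: list[RateEstimate],
    growth_rate: tuple | None = None,
    reserves: tuple = (),
    state_index: int | None = None,
    extracellular_compartment: str = "e",
) -> UnsteadyModel:
    """Matched steady-state control: exometabolomics only, free efflux.

    Only significant rates for *extracellular* metabolites are integrated;
    every intracellular metabolite is held at steady state.  Each
    extracellular metabolite without a measurement receives a free efflux
    reaction with bounds [0, +1000] — secretion allowed, uptake forbidden.
    """
    m = model.copy()
    known = {met.id for met in m.metabolites}
    for r in rates:
        if r.metabolite_id not in known:
            raise DataError(f"rate estimate for unknown metabolite {r.metabolite_id!r}")
    by_met = _dedupe(rates)
    m.remove_reactions(
        [m.reactions.get_by_id(rid) for rid in find_exchange_reactions(m)],
        remove_orphans=False,
    )
    accumulation: dict[str, str] = {}
    for met_id, est in sorted(by_met.items()):
        met = m.metabolites.get_by_id(met_id)
        if met.compartment != extracellular_compartment or not est.significant:
            continue
        accumulation[met_id] = _add_accumulation(m, met, est.b1, est.b2)
    free_efflux: dict[str, str] = {}
    for met in m.metabolites:
        if met.compartment != extracellular_compartment or met.id in accumulation:
            continue
        rxn = cobra.Reaction(EFFLUX_PREFIX + met.id, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        rxn.add_metabolites({met: -1.0})
        rxn.annotation["pseudo"] = "free_efflux"
        m.add_reactions([rxn])
        free_efflux[met.id] = rxn.id
    reserve_map: dict[str, str] = {}
    for met_id in reserves:
        rxn = cobra.Reaction(RESERVE_PREFIX + met_id, lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND)
        rxn.add_metabolites({m.metabolites.get_by_id(met_id): -1.0})
        rxn.annotation["pseudo"] = "reserve"
        m.add_reactions([rxn])
        reserve_map[met_id] = rxn.id
    growth_bounds = _apply_growth_bounds(m, growth_rate)
    return UnsteadyModel(
        model=m,
        accumulation=accumulation,
        measured=set(accumulation),
        free_efflux=free_efflux,
        reserves=reserve_map,
        state_index=state_index,
        mode="fba",
        growth_bounds=growth_bounds,
    )


def save_unsteady(umodel: UnsteadyModel, model_path, manifest_path) -> None:
    """Write the model (JSON dialect) plus a manifest carrying the
    unsteady bookkeeping (accumulation map, sinks, measured set, mode)."""
    write_model(umodel.model, model_path, format="json")
    manifest = {
        "model_file": str(Path(model_path).name),
        "accumulation": umodel.accumulation,
        "relaxation_sinks": {k: list(v) for k, v in umodel.relaxation_sinks.items()},
        "measured": sorted(umodel.measured),
        "free_efflux": umodel.free_efflux,
        "reserves": umodel.reserves,
        "state_index": umodel.state_index,
        "mode": umodel.mode,
        "growth_bounds": list(umodel.growth_bounds) if umodel.growth_bounds else None,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def load_unsteady(model_path, manifest_path) -> UnsteadyModel:
    manifest = json.loads(Path(manifest_path).read_text())
    model = read_model(model_path, format="json")
    return UnsteadyModel(
        model=model,
        accumulation=dict(manifest["accumulation"]),
        relaxation_sinks={k: list(v) for k, v in manifest["relaxation_sinks"].items()},
        measured=set(manifest["measured"]),
        free_efflux=dict(manifest.get("free_efflux", {})),
        reserves=dict(manifest.get("reserves", {})),
        state_index=manifest.get("state_index"),
        mode=manifest.get("mode", "ufba"),
        growth_bounds=tuple(manifest["growth_bounds"]) if manifest.get("growth_bounds") else None,
    )
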