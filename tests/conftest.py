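"""Shared fixtures: small hand-built models and simulated scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cobra

from ufba.synthetic import make_scenario, simulate_timecourse
from ufba.timecourse import TimeCourseDataset, discretize_states, estimate_rates


def build_model(name, mets, rxns):
    """mets: [(id, compartment)]; rxns: [(id, {met: coef}, lb, ub)] or with a
    5th element gene_rule."""
    m = cobra.Model(name)
    m.add_metabolites([cobra.Metabolite(mid, compartment=c) for mid, c in mets])
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({m.metabolites.get_by_id(k): v for k, v in stoich.items()})
        m.add_reactions([r])
        if len(spec) > 4:
            r.gene_reaction_rule = spec[4]
    return m


@pytest.fixture
def chain_model():
    """A -> B -> C with exchanges at both ends."""
    return build_model(
        "chain",
        [("A", "c"), ("B", "c"), ("C", "e")],
        [
            ("EX_A", {"A": 1}, -10, 10),
            ("R1", {"A": -1, "B": 1}, 0, 10),
            ("R2", {"B": -1, "C": 1}, 0, 10),
            ("EX_C", {"C": -1}, -10, 10),
        ],
    )


@pytest.fixture
def interval_model():
    """1-D polytope: IN = OUT in [0, 1]."""
    return build_model(
        "interval", [("A", "c")],
        [("IN", {"A": 1}, 0, 1), ("OUT", {"A": -1}, 0, 1)],
    )


def long_df(rows):
    return pd.DataFrame(
        rows, columns=["metabolite_id", "compartment", "time", "replicate", "concentration"]
    )


def linear_dataset(slopes: dict, times=None, intercept=10.0, noise=0.0,
                   replicates=1, seed=0) -> TimeCourseDataset:
    """Noiseless (or Gaussian-noised) linear profiles, one per metabolite."""
    rng = np.random.default_rng(seed)
    times = np.arange(10.0) if times is None else np.asarray(times, float)
    rows = []
    for met, slope in slopes.items():
        for t in times:
            for rep in range(replicates):
                y = intercept + slope * t + (rng.normal(0, noise) if noise else 0.0)
                rows.append((met, "c", float(t), rep, y))
    return TimeCourseDataset(data=long_df(rows))


@pytest.fixture(scope="session")
def pool_pipeline():
    """One simulated depleting-pool study, processed up to rate estimates."""
    scenario = make_scenario("pool_depletion", seed=1)
    data, truth = simulate_timecourse(scenario)
    windows = discretize_states(data)
    rates = estimate_rates(data, windows[0])
    return scenario, data, truth, windows, rates
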