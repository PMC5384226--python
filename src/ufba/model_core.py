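"""Readers, writers and structural queries for stoichiometric models.

The in-memory container is :class:`cobra.Model`; this module provides the
I/O surface (SBML Level 3 with fbc flux bounds, and the COBRA JSON dialect)
plus the structural queries the uFBA workflow needs — exchange-reaction
detection and stoichiometric-matrix assembly.

Conventions
-----------
* An *exchange* reaction is one whose stoichiometry involves exactly one
  metabolite, or one explicitly annotated with ``annotation["exchange"]``.
  SBML boundary-species dialects collapse to the single-metabolite form on
  read (cobra removes boundary species).
* Exchange flux > 0 means secretion (metabolite leaves the system);
  flux < 0 means uptake.
* Unbounded flux directions are encoded as ±``DEFAULT_BOUND`` (1000).
"""

from __future__ import annotations

import math
from pathlib import Path

import cobra
import cobra.io
import numpy as np

from ufba.errors import ModelFormatError, ModelValidationError

#: Proxy for an unbounded flux direction, matching common model dialects.
DEFAULT_BOUND = 1000.0


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("sbml", "json"):
            raise ModelFormatError(f"unknown model format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelFormatError(
        f"cannot infer model format from suffix {suffix!r}; pass format="
    )


def read_model(path, format: str | None = None) -> cobra.Model:
    """Read a stoichiometric model from SBML or the JSON dialect.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"sbml", "json"}, optional
        Inferred from the suffix (``.xml``/``.sbml`` vs ``.json``) when
        omitted.

    Raises
    ------
    ModelFormatError
        If the file cannot be parsed in the named format.
    ModelValidationError
        If the parsed model violates a structural invariant.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    try:
        if fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except ModelFormatError:
        raise
    except Exception as exc:  # libsbml/json errors vary widely
        raise ModelFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    validate_model(model)
    return model


def write_model(model: cobra.Model, path, format: str | None = None) -> None:
    """Write ``model`` to SBML or the JSON dialect (lossless round-trip of
    ids, stoichiometry, bounds, gene rules and objective)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    validate_model(model)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        cobra.io.save_json_model(model, str(path))


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants of a stoichiometric model.

    Raises :class:`ModelValidationError` on: duplicate metabolite/reaction
    ids, a reaction with empty stoichiometry, inverted bounds, or a
    non-finite bound or coefficient.
    """
    met_ids = [m.id for m in model.metabolites]
    if len(met_ids) != len(set(met_ids)):
        dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
        raise ModelValidationError(f"duplicate metabolite ids: {dup}")
    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
        raise ModelValidationError(f"duplicate reaction ids: {dup}")
    for rxn in model.reactions:
        if len(rxn.metabolites) == 0:
            raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lower_bound > upper_bound"
            )
        for met, coef in rxn.metabolites.items():
            if not math.isfinite(coef):
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has non-finite coefficient on {met.id!r}"
                )


def find_exchange_reactions(model: cobra.Model) -> set[str]:
    """Identify boundary (exchange) reactions.

    A reaction is an exchange iff its stoichiometry involves exactly one
    metabolite, or it carries a truthy ``annotation["exchange"]`` flag.
    The result is invariant under reaction reordering.
    """
    out: set[str] = set()
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1 or rxn.annotation.get("exchange"):
            out.add(rxn.id)
    return out


def stoichiometric_matrix(model: cobra.Model):
    """Dense S matrix with row/column id orderings.

    Returns
    -------
    S : ndarray, shape (n_metabolites, n_reactions)
    met_ids : list of str
    rxn_ids : list of str
    """
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
    return S, met_ids, rxn_ids
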