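"""Exception hierarchy shared by all modules."""


class UFBAError(Exception):
    """Base class for all package errors."""


class ModelFormatError(UFBAError):
    """A model file could not be parsed in the requested format."""


class ModelValidationError(UFBAError):
    """A model violates a structural invariant (duplicate ids, empty
    stoichiometry, inverted bounds, dangling references)."""


class DataError(UFBAError):
    """A time-course dataset violates its invariants or a preprocessing
    precondition (e.g. a metabolite with no observed value)."""


class InfeasibleDataError(UFBAError):
    """The measured rates are inconsistent with the network stoichiometry
    even with every relaxation sink open."""


class SolverError(UFBAError):
    """An optimization backend failed; carries case and iteration context."""
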