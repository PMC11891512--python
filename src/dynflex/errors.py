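"""Exception types shared across the pipeline stages."""


class DynflexError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(DynflexError, ValueError):
    """A cohort or pipeline specification violates its invariants."""


class InvalidWindowError(DynflexError, ValueError):
    """A sliding-window scheme is incompatible with the series length."""


class DegenerateWindowError(DynflexError, ValueError):
    """A region has zero variance inside a window, so Pearson r is undefined."""


class DegenerateLayerError(DynflexError, ValueError):
    """A layer has non-positive total edge weight; the Newman-Girvan null
    model k_i k_j / 2m is undefined there."""


class UndefinedMetricError(DynflexError, ValueError):
    """A temporal metric needs at least two layers (one transition)."""


class ContractError(DynflexError, ValueError):
    """Inputs violate an interface contract (shape, labels, rank...)."""
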