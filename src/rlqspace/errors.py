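"""Exception hierarchy for rlqspace.

All errors raised by the package derive from :class:`RLQSpaceError`, so
callers can catch one type at a pipeline boundary.
"""


class RLQSpaceError(Exception):
    """Base class for all rlqspace errors."""


class InvalidArgumentError(RLQSpaceError, ValueError):
    """A parameter violates its documented precondition."""


class ValidationError(RLQSpaceError, ValueError):
    """Input data violate a structural invariant (bounds, symmetry, ...)."""


class AlignmentError(RLQSpaceError, ValueError):
    """Label sets of the five-matrix bundle cannot be reconciled."""


class ParseError(RLQSpaceError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateInputError(RLQSpaceError, ValueError):
    """Input is structurally valid but statistically degenerate
    (constant values, zero variance after weighting, ...)."""


class DisconnectedGraphError(RLQSpaceError, ValueError):
    """A spatial neighbour graph is not connected; message lists components."""


class FitError(RLQSpaceError, RuntimeError):
    """A model fit failed to converge; message carries diagnostics."""
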