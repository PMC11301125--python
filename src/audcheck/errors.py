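"""Exception types shared across the package."""


class AudcheckError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AudcheckError, ValueError):
    """A file cell could not be interpreted (names the offending row/column)."""


class ValidationError(AudcheckError, ValueError):
    """An object violates one of its structural invariants."""


class BoundaryError(AudcheckError, RuntimeError):
    """An item has no response variation in the data meant to estimate it."""


class IdentificationError(AudcheckError, RuntimeError):
    """The requested model is not identified (e.g. no anchors, singular information)."""


class ConvergenceError(AudcheckError, RuntimeError):
    """An optimisation failed to converge where a converged fit is required."""
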