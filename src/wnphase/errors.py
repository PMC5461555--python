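"""Exception types shared across the package."""


class WnPhaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(WnPhaseError, ValueError):
    """A configuration object violates one of its invariants."""


class InvalidInputError(WnPhaseError, ValueError):
    """An input array or table violates a precondition of an operation."""


class DegenerateNullError(WnPhaseError, ArithmeticError):
    """A surrogate null distribution has zero spread, so no z-score exists."""


class AlignmentError(WnPhaseError, ValueError):
    """Two signals that must share a sampling grid do not."""
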