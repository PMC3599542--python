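"""Exception hierarchy shared across the package."""


class RenschError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RenschError):
    """A file or string could not be parsed into the expected structure."""


class ValidationError(RenschError):
    """Parsed data violated a domain invariant (e.g. non-positive size)."""


class DegenerateInputError(RenschError):
    """Numerically degenerate input: zero variance, constant predictor, etc."""


class InsufficientDataError(RenschError):
    """Fewer observations than the statistic requires."""


class UnsupportedTopologyError(RenschError):
    """Tree is not strictly bifurcating where the analysis requires it."""


class MismatchError(RenschError):
    """Tree tips and trait-table species share no usable overlap."""
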