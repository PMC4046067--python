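"""Exception hierarchy used across the package.

Analysis stages distinguish *bad inputs* (caller errors) from *legitimately
empty or underpowered data* (``InsufficientDataError``), so a pipeline can
log the latter per subject and keep going.
"""


class SomnostatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SomnostatError, ValueError):
    """A parameter set or run configuration violates its invariants."""


class InputError(SomnostatError, ValueError):
    """An operation received malformed input data."""


class InsufficientDataError(SomnostatError):
    """Too few qualifying epochs/samples to compute the requested quantity."""


class ComputationError(SomnostatError, ArithmeticError):
    """A normalization reference or denominator is degenerate (zero/negative)."""


class DegenerateDataError(SomnostatError):
    """Data are degenerate for the requested test (e.g. zero variance)."""
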