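"""Exception hierarchy for amdkit.

All package-specific failures derive from :class:`AmdkitError` so callers can
catch one base class; subclasses distinguish bad user parameters from bad
input data, geometry degeneracies and numerical failures.
"""


class AmdkitError(Exception):
    """Base class for all amdkit errors."""


class ParameterError(AmdkitError, ValueError):
    """A configuration or method parameter is out of its valid range."""


class InputError(AmdkitError, ValueError):
    """Input data violate a documented precondition (non-finite, negative ΔV, ...)."""


class FormatError(AmdkitError, ValueError):
    """A file could not be parsed; carries a line number when available."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class SelectionError(AmdkitError, KeyError):
    """An atom selection did not resolve to exactly one atom."""


class GeometryError(AmdkitError, ValueError):
    """Degenerate geometry (coincident or collinear points) in an angle computation."""


class IntegrationError(AmdkitError, RuntimeError):
    """The integrator diverged; names the offending step."""

    def __init__(self, message: str, step: int | None = None):
        self.step = step
        if step is not None:
            message = f"{message} (step {step})"
        super().__init__(message)


class ComparisonError(AmdkitError, ValueError):
    """Two free-energy profiles share no defined support."""


class NumericalError(AmdkitError, ArithmeticError):
    """A quadrature or log-transform produced no usable result."""
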