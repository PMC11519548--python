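"""Exception hierarchy shared across the package."""


class AirmobError(Exception):
    """Base class for all package-specific errors."""


class InvalidBottleError(AirmobError, ValueError):
    """Bottle geometry, pressure, or temperature outside the physical range."""


class DegenerateSamplingError(AirmobError, ValueError):
    """Sample volume equals or exceeds the headspace volume."""


class UnsupportedGasError(AirmobError, KeyError):
    """A gas lacks the parameters (Henry constant, registry entry) required."""


class RegistryError(AirmobError, KeyError):
    """A species is missing from the formation-energy or gas registry."""


class InsufficientDataError(AirmobError, ValueError):
    """Too few observations for the requested fit."""


class LogDomainError(AirmobError, ValueError):
    """Non-positive value where a logarithm is required."""


class FitFailureError(AirmobError, RuntimeError):
    """Nonlinear fit failed to converge; carries the residual trace."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class ThermodynamicInconsistencyError(AirmobError, ValueError):
    """An endergonic reaction was supplied where an energy source is required."""


class InfiniteQuotientError(AirmobError, ZeroDivisionError):
    """A reactant activity of zero makes the reaction quotient diverge."""


class UndefinedFractionError(AirmobError, ZeroDivisionError):
    """Zero total counts: the isotope fraction is undefined."""


class SchemaError(AirmobError, ValueError):
    """An input table is missing required columns."""


class ParseError(AirmobError, ValueError):
    """A cell in an input table could not be parsed; message carries the line."""
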