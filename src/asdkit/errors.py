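"""Exception hierarchy shared across the analysis stages."""


class AsdkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(AsdkitError):
    """A relaxation model is empty or its parameters violate their bounds."""


class InsufficientDataError(AsdkitError):
    """Too few points for the requested numerical operation."""


class OrderOfOperationsError(AsdkitError):
    """A stage was invoked before its prerequisite (e.g. loss normalisation
    before the derivative loss has been computed)."""


class BoundaryPeakError(AsdkitError):
    """The discrete maximum sits on the edge of the frequency window, so the
    peak position cannot be refined (the peak lies outside the sweep)."""


class DomainError(AsdkitError):
    """An argument is outside the mathematical domain of the model
    (e.g. evaluating a VTFH law at or below the Vogel temperature)."""


class FitFailureError(AsdkitError):
    """A bounded fit did not converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class SchemaError(AsdkitError):
    """An input file does not match the expected column schema."""


class ParseError(AsdkitError):
    """A cell could not be parsed; the message names the offending line."""


class DuplicateRowError(AsdkitError):
    """The same (temperature, frequency) pair appears twice in one file."""


class NoTransitionError(AsdkitError):
    """No heat-capacity step rises above the noise floor of a thermogram."""


class MultipleTransitionsError(AsdkitError):
    """Two or more resolved heat-capacity steps were detected.

    The per-step analyses are attached so callers can inspect both.
    """

    def __init__(self, message: str, transitions=None):
        super().__init__(message)
        self.transitions = transitions or []


class NoSolutionError(AsdkitError):
    """A bracketed root search found no sign change."""


class ScenarioError(AsdkitError):
    """A synthetic-data scenario is internally inconsistent."""


class ConfigError(AsdkitError):
    """A pipeline configuration references missing inputs or bad parameters."""
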