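"""Package-specific exception hierarchy.

Every error raised on purpose by :mod:`affectvar` derives from
:class:`AffectVarError`, so callers can catch domain errors without
swallowing programming mistakes.
"""


class AffectVarError(Exception):
    """Base class for all errors raised by affectvar."""


class ParameterizationError(AffectVarError, ValueError):
    """A generative parameter violates its constraints; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid parameter {field!r}: {message}")


class ScheduleError(AffectVarError, ValueError):
    """A regime schedule has gaps, overlaps or non-positive levels."""


class ConfigurationError(AffectVarError, ValueError):
    """A filter grid or run configuration is invalid."""


class ContractViolationError(AffectVarError):
    """An operation received an input that breaks its stated contract."""


class DegenerateLikelihoodError(AffectVarError):
    """All posterior mass vanished after an update (numerical underflow).

    Usually means the observation lies far outside the configured grid;
    widen the mu or log-SD ranges.
    """


class InsufficientDataError(AffectVarError, ValueError):
    """Too few (consecutive) observations to compute the quantity."""


class DegenerateRegressorError(AffectVarError, ValueError):
    """The lagged regressor has zero variance; the AR(1) slope is undefined."""


class SchemaError(AffectVarError, ValueError):
    """An input table is missing required columns or has unknown items."""


class RowValidationError(AffectVarError, ValueError):
    """A ratings file contains an invalid row; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class CohortSpecError(AffectVarError, ValueError):
    """A cohort/trial generation spec is internally inconsistent."""


class DomainError(AffectVarError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class DesignError(AffectVarError, ValueError):
    """A statistical design cannot be analyzed (e.g. fewer than two groups)."""


class PipelineError(AffectVarError, RuntimeError):
    """The analysis pipeline cannot continue (e.g. no participants left)."""
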