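"""Exception hierarchy.

All validation failures derive from :class:`PlanriskError` so callers (and the
CLI exit-code mapping) can distinguish bad input from I/O trouble.
"""


class PlanriskError(Exception):
    """Base class for all package-specific errors."""


class InvalidDvhError(PlanriskError, ValueError):
    """A dose-volume histogram violates its structural invariants."""


class DomainError(PlanriskError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DvhParseError(PlanriskError, ValueError):
    """A DVH export file could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(PlanriskError, ValueError):
    """A run/panel configuration is inconsistent or incomplete."""


class CohortMismatchError(PlanriskError, ValueError):
    """The two arms of a paired cohort do not contain the same patients."""


class GenerationError(PlanriskError, RuntimeError):
    """The synthetic generator produced an invalid curve (never clipped)."""
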