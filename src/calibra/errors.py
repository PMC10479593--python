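"""Exception hierarchy shared across the package.

Each error class carries the CLI exit code used by :mod:`calibra.cli`.
"""


class CalibraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(CalibraError):
    """Malformed input: schema violation, unknown variable/state, bad value."""

    exit_code = 2

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = list(fields or [])


class InfeasibleParameterError(CalibraError):
    """An effect-size/prevalence combination admits no valid probability table."""

    exit_code = 3

    def __init__(self, message: str, constraint: str | None = None):
        super().__init__(message)
        self.constraint = constraint


class IncompleteKnowledgeError(CalibraError):
    """A variable state lacks a pooled effect or an exposure prevalence."""

    exit_code = 3


class MeasureHeterogeneityError(CalibraError):
    """Effect-size records with mixed measures cannot be pooled together."""

    exit_code = 2


class StateSpaceError(CalibraError):
    """Joint state space too large for exhaustive enumeration."""

    exit_code = 2


class InputOutputError(CalibraError):
    """Unreadable or unwritable path."""

    exit_code = 4
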