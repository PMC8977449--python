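"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PainNMAError(Exception):
    """Base class for all package errors."""


class SchemaError(PainNMAError):
    """An input table is missing required columns or has malformed cells."""


class ValidationError(PainNMAError):
    """One or more domain invariants are violated.

    Carries the full list of violations so callers can report them all at
    once rather than fixing issues one by one.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class DisconnectedNetworkError(ValidationError):
    """The treatment comparison graph is not connected."""


class DegenerateVarianceError(PainNMAError):
    """A pooled standard deviation of zero makes the effect size undefined."""


class ConvergenceError(PainNMAError):
    """MCMC diagnostics exceeded their thresholds.

    The offending diagnostics are attached so the caller can inspect them.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
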