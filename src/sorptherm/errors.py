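"""Exception hierarchy for sorptherm.

All package errors derive from :class:`SorpthermError` so callers can catch
one base class at pipeline boundaries.
"""


class SorpthermError(Exception):
    """Base class for all sorptherm errors."""


class ValidationError(SorpthermError, ValueError):
    """Input data violates a documented precondition or invariant."""


class FormatError(SorpthermError, ValueError):
    """A file is structurally malformed (missing columns, bad header...)."""


class DomainError(SorpthermError, ValueError):
    """A function was evaluated outside its mathematical domain (pole, log of
    a non-positive number, ...)."""


class RangeError(SorpthermError, ValueError):
    """A target value lies outside the attainable image of a function."""


class InversionError(SorpthermError, RuntimeError):
    """Numeric inversion failed (e.g. non-monotone curve on the bracket)."""


class NonConvergenceError(SorpthermError, RuntimeError):
    """No optimizer start converged."""

    def __init__(self, message: str, best_residual_norm: float | None = None):
        super().__init__(message)
        self.best_residual_norm = best_residual_norm


class NumericError(SorpthermError, RuntimeError):
    """A numeric routine (quadrature, root finding) failed to converge."""


class ScenarioError(SorpthermError, ValueError):
    """A synthetic-data scenario is internally inconsistent."""
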