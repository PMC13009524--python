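"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2, ``FitError`` and
``ConvergenceError`` to exit code 3.
"""


class ComdissError(Exception):
    """Base class for all package errors."""


class ValidationError(ComdissError, ValueError):
    """Invalid user input: negative concentration, malformed table, ..."""


class SupersaturationError(ValidationError):
    """Ion product exceeds solubility: the dissolution model does not apply."""


class StateError(ComdissError):
    """Operation requested on an unusable state (e.g. a non-converged solve)."""


class ConvergenceError(ComdissError):
    """Iterative solver did not converge; carries the last residuals."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class FitError(ComdissError):
    """Regression impossible or degenerate (too few points, zero variance)."""
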