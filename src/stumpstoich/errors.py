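"""Exception hierarchy for the stump-stoichiometry pipeline.

``StoichError`` is the common base so callers (and the CLI) can separate
configuration problems (:class:`ConfigError`, exit code 2) from data problems
(everything else, exit code 3).
"""

from __future__ import annotations


class StoichError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StoichError):
    """Invalid configuration (bad form name, contradictory options, ...)."""


class FormatError(StoichError):
    """A table does not conform to the expected schema."""


class EmptyInputError(StoichError):
    """An operation received no usable rows/samples."""


class InsufficientDataError(StoichError):
    """Fewer qualifying samples than a selection rule requires."""


class UnitMismatchError(StoichError):
    """The same element is expressed in different units across tables."""


class ElementDivisionError(StoichError):
    """A ratio denominator (or initial concentration) is zero; names the element."""


class AlignmentError(StoichError):
    """Two tables that must share a key set do not."""


class DegenerateDesignError(StoichError):
    """Regression design is degenerate (e.g. constant predictor)."""


class ConvergenceError(StoichError):
    """Nonlinear fit failed to converge; carries the initialization fit."""

    def __init__(self, message: str, init_fit=None):
        super().__init__(message)
        self.init_fit = init_fit


class LogDomainError(StoichError):
    """A log transform was requested for a non-positive value."""
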