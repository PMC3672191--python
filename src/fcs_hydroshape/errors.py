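"""Exception hierarchy.

All user-facing errors derive from :class:`FcsHydroError` so that callers
(and the CLI) can distinguish validation problems (:class:`DomainError`,
:class:`UsageError`) from runtime failures (:class:`FitError`).
"""


class FcsHydroError(Exception):
    """Base class for all package errors."""


class DomainError(FcsHydroError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class ModelError(DomainError):
    """An FCS model object is structurally invalid (e.g. empty species list)."""


class UsageError(FcsHydroError, ValueError):
    """An operation was called in a way its contract forbids."""


class FitError(FcsHydroError, RuntimeError):
    """A fit could not be set up or evaluated (e.g. degenerate input curve)."""


class NoProlateSolutionError(DomainError):
    """Measured D is at least the equal-volume sphere value: no prolate shape exists."""


class OutOfModelError(DomainError):
    """Measured D requires an axial ratio below the supported range (p < 1e-4)."""


class NormalizationError(FcsHydroError, ValueError):
    """Correlation normalization is undefined (zero mean intensity)."""
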