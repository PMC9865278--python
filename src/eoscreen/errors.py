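"""Exception and warning types shared across the package."""


class EoscreenError(Exception):
    """Base class for all package-specific errors."""


class OutOfRangeError(EoscreenError, ValueError):
    """A retention time falls outside the alkane ladder span."""


class AnnotationError(EoscreenError, ValueError):
    """A compound lacks a required class annotation."""


class UnknownComponentError(EoscreenError, KeyError):
    """A named component is not present in the composition table."""


class InvalidReadingError(EoscreenError, ValueError):
    """A plate reading violates a precondition (e.g. non-positive blank)."""


class DegenerateDesignError(EoscreenError, ValueError):
    """An input design is too degenerate to analyse (constant column, <4 dose levels, ...)."""


class DegenerateCriterionError(EoscreenError, ValueError):
    """A decision-matrix criterion column is all zero."""


class DegenerateIdealError(EoscreenError, ValueError):
    """Positive and negative ideal solutions coincide for some alternative."""


class UnusableFitError(EoscreenError, ValueError):
    """An operation requires a converged fit but the fit did not converge."""


class ConfigError(EoscreenError, ValueError):
    """A run configuration is invalid (unknown keys, missing files, bad values)."""


class ProOxidantWarning(UserWarning):
    """Scavenging percentage is negative (sample absorbs more than blank)."""


class BelowCalibrationWarning(UserWarning):
    """A Trolox-equivalent value fell below the calibration range (negative)."""


class ProliferationWarning(UserWarning):
    """Viability above 100% of vehicle (apparent proliferation)."""


class NotCrossedWarning(UserWarning):
    """A fitted dose-response curve never crosses the 50% viability line."""


class NegativeCriterionWarning(UserWarning):
    """Decision matrix contains negative entries; ideal-point semantics assume non-negative data."""


class TieWarning(UserWarning):
    """Tied closeness coefficients; ranks assigned stably by input order."""


class DegenerateResponseWarning(UserWarning):
    """Response vector is (near-)constant; importances are not meaningful."""
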