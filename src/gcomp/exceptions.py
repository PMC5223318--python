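"""Exception hierarchy for gcomp.

All package-raised errors derive from :class:`GcompError` so callers can
distinguish user/data problems from programming bugs with one ``except``.
"""

from __future__ import annotations


class GcompError(Exception):
    """Base class for all errors raised by gcomp."""


class ConfigurationError(GcompError):
    """A run configuration is malformed (missing column, unknown key, bad flag)."""


class DataError(GcompError):
    """The input table violates the data contract (missing values, non-binary coding)."""


class FitError(GcompError):
    """The outcome model could not be estimated.

    Parameters
    ----------
    message:
        Human-readable description.
    columns:
        Design columns implicated in the failure (collinear or separating),
        when identifiable.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class SeparationError(FitError):
    """Complete or quasi-complete separation: the logistic MLE does not exist."""


class PositivityError(GcompError):
    """A covariate stratum required by a standardization formula has no units
    in the conditioning treatment arm."""

    def __init__(self, message: str, stratum: tuple = ()):
        super().__init__(message)
        self.stratum = tuple(stratum)


class DegenerateOddsError(GcompError):
    """A marginal risk of exactly 0 or 1 makes the odds ratio undefined."""


class EstimationError(GcompError):
    """A point estimate could not be formed (e.g. an empty counterfactual arm)."""


class BootstrapError(GcompError):
    """Too many bootstrap replicates failed for the resampling distribution
    to be trusted."""

    def __init__(self, message: str, n_failed: int = 0, n_total: int = 0):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_total = n_total


class DegenerateDrawsError(GcompError):
    """Bootstrap draws are all identical; a BCa interval is undefined."""
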