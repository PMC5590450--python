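"""Exception hierarchy for fedbatch_ukf."""

from __future__ import annotations


class FedbatchUKFError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedbatchUKFError):
    """Invalid configuration value, key, or combination."""


class PropagationError(FedbatchUKFError):
    """ODE propagation failed.

    Attributes
    ----------
    last_valid_time : float or None
        Last time (h) at which a valid state was available.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class FitError(FedbatchUKFError):
    """Parameter fitting did not converge.

    Carries the best parameters seen so far in ``best_params``.
    """

    def __init__(self, message: str, best_params=None, report=None):
        super().__init__(message)
        self.best_params = best_params
        self.report = report


class TrainingError(FedbatchUKFError):
    """Observation-model training failed (degenerate data, bad grid...)."""


class NumericalError(FedbatchUKFError):
    """Linear-algebra failure that jitter regularization could not repair."""


class UpdateError(FedbatchUKFError):
    """Measurement update failed (e.g. singular innovation covariance)."""


class FilterError(FedbatchUKFError):
    """A filter run aborted; ``partial_trajectory`` holds results so far."""

    def __init__(self, message: str, partial_trajectory=None):
        super().__init__(message)
        self.partial_trajectory = partial_trajectory


class FormatError(FedbatchUKFError):
    """A file does not match its expected schema (e.g. missing column)."""


class DataError(FedbatchUKFError):
    """File parsed but content is invalid; ``row`` is the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
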