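"""Exception hierarchy.

``ValidationError`` covers bad inputs/configuration (CLI exit code 1);
``ComputeError`` covers failures arising during estimation (exit code 2).
"""


class KetsimError(Exception):
    """Base class for all package errors."""


class ValidationError(KetsimError, ValueError):
    """Invalid configuration, input table, or parameter value."""


class GridMismatchError(ValidationError):
    """Volumes that must share a voxel grid (and affine) do not."""


class ThresholdError(ValidationError):
    """A threshold produced a degenerate result (e.g. an empty seed mask)."""


class ComputeError(KetsimError, RuntimeError):
    """Estimation failed (rank deficiency, undefined statistic, ...)."""


class EstimationError(ComputeError):
    """A model fit could not be carried out on the given data."""


class UndefinedStatisticError(ComputeError):
    """A statistic is undefined for the given input (e.g. constant vector)."""
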