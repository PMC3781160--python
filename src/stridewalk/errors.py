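"""Exceptions raised by the walker, the return map and the analysis battery."""

from __future__ import annotations


class StrideWalkError(Exception):
    """Base class for all package errors."""


class GeometryError(StrideWalkError):
    """The four-bar linkage is singular or the release angle is unreachable."""


class PhaseViolationError(StrideWalkError):
    """A state was used in a gait phase where it is not valid (e.g. psi > mu)."""


class GaitFailureError(StrideWalkError):
    """The walker fell (the stance leg stopped before heel strike).

    Attributes
    ----------
    stride_index : int
        Index of the stride during which the failure occurred (0-based).
    partial : StrideSeries or None
        The strides completed before the failure, flagged ``complete=False``.
    """

    def __init__(self, message: str, stride_index: int = -1, partial=None):
        super().__init__(message)
        self.stride_index = stride_index
        self.partial = partial


class InfeasibleStateError(StrideWalkError):
    """A return-map state carries too little energy to complete a step."""


class DegenerateSeriesError(StrideWalkError):
    """A statistic is undefined for the given series (e.g. constant input)."""


class CalibrationError(StrideWalkError):
    """Root-finding for a calibration target failed to bracket a solution."""
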