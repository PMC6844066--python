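"""Exception hierarchy for pulmoflow.

All package errors derive from :class:`PulmoflowError` so callers can catch
everything with one clause; the subclasses mirror the distinct failure
contracts of the generator, the quantification stage and the statistics.
"""


class PulmoflowError(Exception):
    """Base class for all pulmoflow errors."""


class InvalidParameterError(PulmoflowError, ValueError):
    """A parameter violates a precondition (non-positive RR interval, too few frames, ...)."""


class InvalidInputError(PulmoflowError, ValueError):
    """Input data are structurally invalid (dimension mismatch, empty mask, missing vessel)."""


class AlignmentError(InvalidInputError):
    """Flow curves do not share frame count and RR interval."""


class InfeasibleTargetError(PulmoflowError):
    """The requested volume-variation target would force implausibly negative venous flow."""


class AliasingRiskError(PulmoflowError):
    """The implied peak velocity exceeds the velocity-encoding limit; generation refuses."""


class DegenerateFitError(PulmoflowError):
    """Background-phase surface fit is rank deficient (static pixels collinear)."""


class PropagationFailureError(PulmoflowError):
    """ROI propagation lost the vessel. Carries the failing frame index."""

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(message or f"ROI propagation lost the vessel at frame {frame}")


class DegenerateTestError(PulmoflowError):
    """A statistical test cannot be performed (e.g. all paired differences are zero)."""


class InsufficientDataError(PulmoflowError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedPercentError(PulmoflowError, ZeroDivisionError):
    """A percent difference is undefined because a pair averages to zero."""
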