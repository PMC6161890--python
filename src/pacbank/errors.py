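"""Exception hierarchy.

The CLI maps :class:`ParameterError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is an ordinary traceback.
"""


class PacbankError(Exception):
    """Base class for all pacbank-specific errors."""


class ParameterError(PacbankError, ValueError):
    """A caller-supplied parameter violates its documented contract."""


class PlanningError(ParameterError):
    """A filter-bank plan cannot be realized with the requested geometry."""


class AlignmentError(ParameterError):
    """Phase/amplitude series rates are not integer-related."""


class SegmentLengthError(ParameterError):
    """A segment's length does not match the plan it is applied to."""


class DataError(PacbankError, ValueError):
    """Input data is malformed (non-numeric, NaN, missing metadata...)."""


class DataSufficiencyWarning(UserWarning):
    """Not enough samples to populate the phase-amplitude distribution."""
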