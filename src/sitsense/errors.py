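"""Exception hierarchy for sitsense.

All library errors derive from :class:`SitsenseError` so callers can catch
one base class; user-input problems additionally derive from ``ValueError``.
"""


class SitsenseError(Exception):
    """Base class for all sitsense errors."""


class InvalidGeometryError(SitsenseError, ValueError):
    """A joint segment or gaze vector is degenerate (zero length)."""


class InvalidBoxError(SitsenseError, ValueError):
    """A bounding box has non-positive width/height or non-finite corners."""


class AlignmentError(SitsenseError, ValueError):
    """Per-frame inputs do not share the same frame index."""


class InsufficientDataError(SitsenseError, ValueError):
    """Too few valid rows/samples for the requested operation."""


class NumericalDegeneracyError(SitsenseError, ArithmeticError):
    """A covariance is irreparably non-SPD or all densities underflowed."""


class SequencingError(SitsenseError, ValueError):
    """A frame-label sequence is unordered or has gaps."""


class SpecError(SitsenseError, ValueError):
    """A synthetic posture-class specification is infeasible."""


class LabelingError(SitsenseError, ValueError):
    """A cluster mean implies invalid geometry and cannot be labelled."""
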