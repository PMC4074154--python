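"""Exception hierarchy for voltdiff."""


class VoltdiffError(Exception):
    """Base class for all voltdiff errors."""


class InvalidConditionsError(VoltdiffError):
    """Experiment conditions violate an invariant (e.g. dE does not divide the window)."""


class InvalidMechanismError(VoltdiffError):
    """Mechanism specification is incomplete or inconsistent for its kind."""


class NumericalFailureError(VoltdiffError):
    """A linear solve failed or produced non-finite values."""


class NoPeakError(VoltdiffError):
    """The forward branch of a voltammogram has no interior current extremum."""


class DimensionMismatchError(VoltdiffError):
    """Array shapes are incompatible with the trained model or operation."""


class InvalidInputError(VoltdiffError):
    """A scalar argument is outside its admissible range."""


class GridMismatchError(VoltdiffError):
    """Two voltammograms do not share the same potential grid."""


class DegenerateTraceError(VoltdiffError):
    """A current trace is constant and cannot be scaled to [-1, 1]."""


class NonPositiveDefiniteError(VoltdiffError):
    """A covariance matrix could not be factorized even after jitter escalation."""
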