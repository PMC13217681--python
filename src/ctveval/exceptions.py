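"""Exception hierarchy for contour-evaluation errors.

Every error raised by this package derives from :class:`CtvEvalError`, so
pipeline code can distinguish evaluation problems from programming errors.
Metric code raises rather than returning sentinel values: a silent 0 or NaN
for an empty mask would corrupt downstream cohort statistics.
"""


class CtvEvalError(Exception):
    """Base class for all errors raised by ctveval."""


class InvalidGeometryError(CtvEvalError):
    """Mask geometry is unusable: non-positive spacing, shape mismatch,
    non-axis-aligned orientation, or a shape that does not fit its grid."""


class UndefinedMetricError(CtvEvalError):
    """A metric is mathematically undefined for the given input, e.g. any
    surface or overlap measure involving an empty mask."""


class InvalidParameterError(CtvEvalError):
    """A parameter is outside its admissible range (percentile, n, or an
    unknown metric name)."""


class InsufficientDataError(CtvEvalError):
    """Too few observations for the requested summary or test."""


class InvalidDataError(CtvEvalError):
    """Input values violate a data contract (e.g. non-positive volumes)."""


class DegenerateDataError(CtvEvalError):
    """Data are degenerate for the requested test: all paired differences
    zero, or zero variance where a scale estimate is needed."""


class DegenerateOutputError(CtvEvalError):
    """A simulation step produced an unusable result, e.g. a perturbation
    eroded a mask to emptiness."""


class EmptyCohortError(CtvEvalError):
    """No observers survive quality control; nothing to analyse."""
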