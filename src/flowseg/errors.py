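"""Exception hierarchy for flowseg.

All errors raised by the library derive from :class:`FlowsegError` so callers
can catch the package's failures with a single handler.
"""


class FlowsegError(Exception):
    """Base class for all flowseg errors."""


class DimensionError(FlowsegError):
    """Frames or masks with inconsistent shapes."""


class EmptyStackError(FlowsegError):
    """A stack with no readable frames."""


class ValidationError(FlowsegError):
    """Input violates an operation precondition (non-binary mask, etc.)."""


class ParameterError(FlowsegError):
    """A parameter value outside its admissible range."""


class DegenerateLabelingError(FlowsegError):
    """The displacement-magnitude field has no separable high/low regimes
    (e.g. a constant field), so no self-labels can be produced."""


class TuningFailureError(FlowsegError):
    """Adaptive threshold reduction exhausted its iterations without meeting
    the stopping criteria.  Carries the best label map seen so the caller may
    proceed with a warning."""

    def __init__(self, message, best_labels=None, iterations=0):
        super().__init__(message)
        self.best_labels = best_labels
        self.iterations = iterations


class EmptyClassError(FlowsegError):
    """A training table is missing one of the two classes."""


class SizeEstimationError(FlowsegError):
    """Mean cell area could not be estimated from the motion mask."""


class ConfigurationError(FlowsegError):
    """An invalid synthetic-movie or run configuration."""
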