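"""Exception hierarchy shared across the package."""


class RehabPredictError(Exception):
    """Base class for all package errors."""


class SchemaError(RehabPredictError):
    """A table is missing mandatory columns or is empty."""


class CohortValidationError(RehabPredictError):
    """A record violates a score range or uniqueness constraint."""


class ParameterError(RehabPredictError):
    """An operation was called with an out-of-range parameter."""


class SegmentationError(RehabPredictError):
    """Phase segmentation could not locate the required force events."""


class DegenerateSegmentError(RehabPredictError):
    """A movement segment carries no usable signal (zero length/path)."""


class InsufficientDataError(RehabPredictError):
    """Fewer valid movements than required to aggregate a metric."""


class LabelingError(RehabPredictError):
    """A pre/post score pair needed for responder labeling is missing."""


class FeatureUnavailableError(RehabPredictError):
    """A requested feature set cannot be populated from the given tables."""


class CrossValidationError(RehabPredictError):
    """The cohort cannot support the requested cross-validation scheme."""
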