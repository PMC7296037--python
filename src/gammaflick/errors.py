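"""Exception hierarchy shared across the analysis stages."""


class GammaflickError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GammaflickError, ValueError):
    """A parameter violates its documented constraint."""


class ShapeError(GammaflickError, ValueError):
    """Array lengths or shapes are incompatible for the requested operation."""


class BandRangeError(GammaflickError, ValueError):
    """A frequency band falls outside the usable frequency range."""


class InsufficientEpochsError(GammaflickError, RuntimeError):
    """Fewer artifact-free epochs are available than were requested.

    The number of clean, non-overlapping windows that could be placed is
    exposed as ``available`` so callers can decide whether to proceed
    with a smaller sample.
    """

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(
            f"requested {requested} artifact-free epochs but only "
            f"{available} non-overlapping clean windows are available"
        )


class FeatureNotFoundError(GammaflickError, RuntimeError):
    """No evoked deflection was detectable above the noise floor."""


class NoDecayError(GammaflickError, RuntimeError):
    """A destaining curve shows no measurable decline."""


class DegenerateTraceError(GammaflickError, ValueError):
    """A fluorescence trace collapses to nothing after residual subtraction."""


class TraceValidationError(GammaflickError, ValueError):
    """A trace table or sidecar failed validation."""


class PipelineUsageError(GammaflickError, ValueError):
    """The pipeline configuration is unusable (unknown stage, empty stage list...)."""
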