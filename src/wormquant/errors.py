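"""Exception hierarchy shared across the pipeline stages."""


class WormquantError(Exception):
    """Base class for all package errors."""


class ParameterError(WormquantError, ValueError):
    """A model or generator parameter is non-finite or out of range."""


class GenerationError(WormquantError):
    """Synthetic rendering failed (e.g. the cell would leave the frame)."""


class TrackingLostError(WormquantError):
    """ROI tracking failed; carries the frame index where it happened."""

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(message or f"ROI tracking lost at frame {frame}")


class BaselineError(WormquantError):
    """The baseline window of a ratio trace is unusable."""


class CoverageError(WormquantError):
    """A trace does not cover the requested scoring interval."""


class QCError(WormquantError):
    """A day-level quality-control gate could not be evaluated."""


class SchemaError(WormquantError):
    """A configuration file failed validation.

    ``keys`` lists the offending configuration keys.
    """

    def __init__(self, keys, message: str | None = None):
        self.keys = list(keys)
        super().__init__(message or f"invalid configuration keys: {', '.join(self.keys)}")
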