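"""Exception hierarchy.

Every error raised by flagkin derives from :class:`FlagkinError`, so callers
(e.g. the pipeline's per-frame QC loop) can catch analysis failures without
masking programming errors.
"""


class FlagkinError(Exception):
    """Base class for all flagkin errors."""


class InvalidParameterError(FlagkinError, ValueError):
    """A parameter violates its documented invariant."""


class GeometryError(FlagkinError):
    """A rendered flagellum does not fit the requested canvas."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class SegmentationError(FlagkinError):
    """Segmentation did not yield exactly one flagellum component."""

    def __init__(self, n_components: int):
        super().__init__(
            f"expected exactly 1 flagellum component, found {n_components}"
        )
        self.n_components = n_components


class TraceError(FlagkinError):
    """Centerline extraction failed for a frame (e.g. self-crossing skeleton)."""


class GridError(FlagkinError):
    """Arrays do not share the required uniform grid."""


class InsufficientCyclesError(FlagkinError):
    """Too few curvature turning points to estimate a beat frequency."""


class SectionOutOfRangeError(FlagkinError):
    """A tail section lies entirely beyond the traced length."""


class InvalidAmplitudeError(FlagkinError, ValueError):
    """Negative amplitude passed to the flexibility classifier."""


class RankError(FlagkinError):
    """Waveform is constant in time; shape modes are undefined."""


class DegenerateCycleError(FlagkinError):
    """Shape-cycle coefficients are collinear or have zero variance."""


class SolverError(FlagkinError):
    """The envelope solver could not reach the requested amplitude."""


class NumericError(FlagkinError):
    """Non-finite intermediate encountered (usually a tracing artifact)."""

    def __init__(self, message: str, frame: int | None = None, station: int | None = None):
        super().__init__(message)
        self.frame = frame
        self.station = station


class InsufficientRecordError(FlagkinError):
    """Record shorter than one full beat period."""


class EmptySetError(FlagkinError):
    """An aggregation was requested over an empty record set."""


class InsufficientGroupsError(FlagkinError):
    """Fewer than two animals per group remain for comparison."""
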