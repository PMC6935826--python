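"""Exception hierarchy for spineload.

All package errors derive from :class:`SpineLoadError` so callers can catch
one base class; the CLI maps subclasses onto its exit codes.
"""


class SpineLoadError(Exception):
    """Base class for all spineload errors."""


class FormatError(SpineLoadError):
    """A marker/rhythm/results file does not parse under the named dialect."""


class MissingLandmarkError(SpineLoadError):
    """A required bony landmark is absent from the marker set."""

    def __init__(self, landmark: str, message: str | None = None):
        self.landmark = landmark
        super().__init__(message or f"required landmark {landmark!r} is missing")


class InsufficientEventsError(SpineLoadError):
    """Fewer than two same-leg heel strikes: no complete cycle exists."""


class DegenerateCycleError(SpineLoadError):
    """A cycle with fewer than two frames cannot be time-normalized."""


class GeometryError(SpineLoadError):
    """Degenerate marker or fascicle geometry (collinear pelvis cluster,
    zero-length posed fascicle, ...)."""


class NoMotionError(SpineLoadError):
    """Total lumbar excursion never exceeds the small-angle threshold, so
    rhythm fractions are undefined."""


class InvalidRhythmError(SpineLoadError):
    """Rhythm fractions are negative or do not sum to one."""


class SchemaError(SpineLoadError):
    """A model/config table violates its schema (unknown segment, negative
    mass or strength, ...)."""


class InfeasibleError(SpineLoadError):
    """The recruitment LP has no tensile-force solution for the demanded
    moments."""

    def __init__(self, message: str, joints: tuple[str, ...] = ()):
        self.joints = joints
        super().__init__(message)


class AggregationError(SpineLoadError):
    """Reports with mixed activity labels or intervention kinds cannot be
    pooled."""


class ConfigError(SpineLoadError):
    """Pipeline configuration is invalid; message names the offending field."""


class DependencyError(SpineLoadError):
    """A pipeline stage was requested before its upstream outputs exist."""
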