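"""Exception hierarchy for the pillar-tracking pipeline.

Every stage raises a subclass of :class:`PillarTrackError` so that the
batch runner can isolate per-movie failures and report the failing stage.
"""


class PillarTrackError(Exception):
    """Base class for all pipeline errors."""


class MovieLoadError(PillarTrackError):
    """Raised when a frame folder cannot be read into a movie."""


class SegmentationError(PillarTrackError):
    """Raised when automatic pillar segmentation fails.

    The message always suggests the external-mask fallback, since a user
    can supply manually or externally generated binary masks instead.
    """


class MaskError(PillarTrackError):
    """Raised for invalid pillar masks (empty, non-binary, wrong shape)."""


class TrackingError(PillarTrackError):
    """Raised when feature detection or optical-flow tracking fails."""


class BeatAnalysisError(PillarTrackError):
    """Raised when the displacement series cannot be segmented into beats,
    e.g. fewer than 2 complete beats in the movie."""


class MechanicsError(PillarTrackError):
    """Raised for invalid mechanical geometry or failed width measurement."""


class MetricsError(PillarTrackError):
    """Raised when a contractility metric cannot be computed."""


class ConfigError(PillarTrackError):
    """Raised for invalid or inconsistent run configuration."""
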