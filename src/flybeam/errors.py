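"""Exception hierarchy.

Every error raised by this package derives from :class:`FlybeamError`, so
callers (and the CLI) can catch one base class and report per-chamber
failures without aborting a whole run.
"""


class FlybeamError(Exception):
    """Base class for all flybeam errors."""


class InvalidLayoutError(FlybeamError):
    """Arena layout leaves no usable area for the crop grid."""


class OutOfChamberError(FlybeamError):
    """A point expected inside the chamber rectangle lies outside it."""


class TrackingFormatError(FlybeamError):
    """A tracking table does not follow the expected three-row CSV dialect."""


class UnsupportedLayoutError(TrackingFormatError):
    """The tracking table contains more than one tracked body part."""


class TrackingParseError(TrackingFormatError):
    """A data cell in a tracking table could not be parsed as a number."""


class ScheduleRangeError(FlybeamError):
    """A queried time lies outside the light schedule's coverage."""


class GeometryInferenceError(FlybeamError):
    """Too few confident detections to infer chamber limits."""


class DegenerateGeometryError(FlybeamError):
    """Inferred chamber extent is too small to be a real chamber."""


class UnrecoverableSeriesError(FlybeamError):
    """All frames of a series are flagged; nothing to interpolate from."""


class GridAlignmentError(FlybeamError):
    """Per-fly binned series do not share a common bin grid."""


class StatisticUndefinedError(FlybeamError):
    """A test statistic is undefined (degenerate group sizes or variance)."""


class InsufficientDaysError(FlybeamError):
    """Recording does not contain the requested number of complete cycles."""


class ConfigError(FlybeamError):
    """Experiment configuration file is missing keys or inconsistent."""
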