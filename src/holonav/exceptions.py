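"""Exception and warning hierarchy.

Every error raised on bad input derives from :class:`HolonavError` so callers
(and the CLI) can catch one base class and map it to an exit status.
"""


class HolonavError(Exception):
    """Base class for all errors raised by holonav."""


class InvalidInputError(HolonavError, ValueError):
    """Non-finite coordinates, empty lists, malformed values."""


class CorrespondenceError(HolonavError, ValueError):
    """Paired point sets whose labels or lengths do not match."""


class DegenerateConfigurationError(HolonavError, ValueError):
    """Fewer than three points, or a collinear constellation: the rigid
    pose is underdetermined."""


class SceneStateError(HolonavError, RuntimeError):
    """Operation requires a scene state (e.g. a stored lock) that is absent."""


class FormatError(HolonavError, ValueError):
    """A file could not be parsed in the expected format."""


class TrackingQualityWarning(UserWarning):
    """Marker-fit RMS exceeded the quality threshold; the pose is still
    returned (tracking degrades, it does not halt)."""


class ConvergenceWarning(UserWarning):
    """Iterative registration failed to reduce the error below its
    starting value."""
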