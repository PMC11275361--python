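"""Exception hierarchy shared by the tracking pipeline."""


class ProbeTrackError(Exception):
    """Base class for all package-specific errors."""


class NotARotation(ProbeTrackError):
    """Matrix is not orthonormal with determinant +1."""


class MarkerDoesNotFit(ProbeTrackError):
    """Marker square with the requested inset exceeds the pentagonal face."""


class UnknownMarkerId(ProbeTrackError, KeyError):
    """Marker id not present in the cluster model."""


class BehindCamera(ProbeTrackError):
    """Point(s) at non-positive camera-frame depth cannot be projected."""


class DegenerateConfiguration(ProbeTrackError):
    """Too few or geometrically degenerate correspondences/points."""


class NoConsensus(ProbeTrackError):
    """RANSAC found no model reaching the minimum inlier count."""


class CollinearityViolation(ProbeTrackError):
    """Wire echoes deviate too far from a straight line."""


class DepthInconsistent(ProbeTrackError):
    """Wire-cross depth implied by pixels disagrees with the nominal depth."""


class SnapshotInvalid(ProbeTrackError):
    """Calibration snapshot rejected (e.g. multiple proximal echoes)."""


class WindowTooLarge(ProbeTrackError):
    """Savitzky-Golay window exceeds the stream length."""


class OutOfRange(ProbeTrackError):
    """Resampling time outside the source stream's span."""


class TimestampMismatch(ProbeTrackError):
    """Streams that must share timestamps do not."""


class ShapeMismatch(ProbeTrackError):
    """Candidate/reference arrays have incompatible shapes."""


class MalformedHeader(ProbeTrackError):
    """Pose CSV header does not match the expected column list."""


class NonMonotoneTimestamps(ProbeTrackError):
    """Timestamps are not strictly increasing."""


class DuplicateMarkerId(ProbeTrackError):
    """A marker id appears twice within one observation frame."""


class MalformedRecord(ProbeTrackError):
    """A JSON-lines observation record does not parse or validate."""


class ConfigurationError(ProbeTrackError):
    """Pipeline configuration invalid (missing file, bad value)."""
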