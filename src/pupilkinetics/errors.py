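"""Exception hierarchy for pupilkinetics."""


class PupilKineticsError(Exception):
    """Base class for all package errors."""


class SegmentFormatError(PupilKineticsError):
    """Malformed or inconsistent per-frame segmentation record."""


class EmptyMaskError(PupilKineticsError):
    """A binary mask with no foreground pixels where one is required."""


class NoValidFramesError(PupilKineticsError):
    """No frame survived the validity filter; widths cannot be interpolated."""


class SignalLengthError(PupilKineticsError):
    """Signal too short for the requested filter (padding infeasible)."""


class DegenerateSignalError(PupilKineticsError):
    """Width signals violate the anatomical assumptions (e.g. non-positive DM)."""


class AnnotationError(PupilKineticsError):
    """Ground-truth annotation violates its invariants (overlap, ordering)."""


class PlacementError(PupilKineticsError):
    """Simulated reactions could not be placed without overlap."""


class GeometryError(PupilKineticsError):
    """Requested synthetic eye does not fit in the frame."""


class ConfigError(PupilKineticsError):
    """Invalid configuration (empty grid, bad parameter range)."""
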