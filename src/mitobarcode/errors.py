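"""Exception hierarchy.

Every error raised by the library derives from :class:`MitobarcodeError`,
split into three broad classes so callers (and the CLI) can map them to
distinct exit codes: malformed input files, invalid parameters/usage, and
failures arising during computation.
"""


class MitobarcodeError(Exception):
    """Base class for all library errors."""


class FormatError(MitobarcodeError):
    """A file could not be parsed as the requested format."""


class AlignmentShapeError(FormatError):
    """Records requested as an alignment do not have equal lengths."""


class LabelParseError(MitobarcodeError):
    """A sequence label contains no usable taxon name."""


class BoundsError(MitobarcodeError):
    """An interval lies outside the coordinate system it refers to."""


class ParameterError(MitobarcodeError):
    """An argument or configuration value is invalid."""


class UndefinedDistanceError(MitobarcodeError):
    """A distance is undefined (zero comparable sites) -- distinct from
    saturation, which yields an infinite sentinel rather than an error."""


class EmptyResultError(MitobarcodeError):
    """An operation produced no results after filtering."""


class IncompleteMatrixError(MitobarcodeError):
    """A distance matrix contains missing or saturated entries where a
    complete matrix is required."""

    def __init__(self, message: str, offending_pairs=None):
        super().__init__(message)
        self.offending_pairs = list(offending_pairs or [])


class SerializationError(MitobarcodeError):
    """An object cannot be written in the requested format."""
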