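"""Exception hierarchy for the QC pipeline.

Every error raised by plexqc derives from :class:`QCError` so callers can
catch pipeline problems without masking programming errors.
"""


class QCError(Exception):
    """Base class for all plexqc errors."""


class SchemaError(QCError):
    """An input file is missing required columns/channels."""


class ConsistencyError(QCError):
    """Cross-file invariants are violated (e.g. table cell ids absent from mask)."""


class ValidationError(QCError):
    """A value inside an input violates its declared invariants."""


class ParameterError(QCError):
    """A user-supplied parameter is out of its valid range."""


class GeometryError(QCError):
    """An ROI polygon or artifact geometry is malformed."""


class PlacementError(QCError):
    """The synthetic generator cannot place cells at the requested density."""


class InsufficientDataError(QCError):
    """Too few cells remain for the requested computation."""


class StaleCheckpointError(QCError):
    """A checkpoint was produced under a different configuration."""


class ConfigError(QCError):
    """The pipeline configuration file is invalid."""
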