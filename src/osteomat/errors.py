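"""Exception hierarchy for osteomat.

All package-specific failures derive from :class:`OsteomatError` so callers
can catch analysis errors without masking programming errors.
"""


class OsteomatError(Exception):
    """Base class for all osteomat errors."""


class CalibrationError(OsteomatError):
    """Invalid grey-level calibration (reversed/equal reference greys, bad anchors)."""


class ConfigurationError(OsteomatError):
    """Missing or inconsistent configuration (e.g. unknown pixel size)."""


class EmptyCompartmentError(OsteomatError):
    """A compartment contains no usable (mineralized / in-mask) pixels."""


class GridMismatchError(OsteomatError):
    """Histogram curves to be pooled do not share the same bin grid."""


class CoverageError(OsteomatError):
    """A spectrum does not cover the requested wavenumber range."""


class BandShapeError(OsteomatError):
    """A band has no interior maximum or half-maximum crossings inside its window."""


class DegenerateSpectrumError(OsteomatError):
    """A denominator band area is zero (or not finite)."""


class InsufficientDataError(OsteomatError):
    """Too few observations for a statistical test."""


class UndefinedCorrelationError(OsteomatError):
    """Correlation of a zero-variance variable is undefined."""


class PhantomSpecError(OsteomatError):
    """Invalid synthetic phantom specification (e.g. overlapping lacunae)."""
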