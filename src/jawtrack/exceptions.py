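"""Exception hierarchy shared across the package."""


class JawTrackError(Exception):
    """Base class for all jawtrack errors."""


class InvalidInputError(JawTrackError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class DegenerateConfigurationError(JawTrackError, ValueError):
    """Geometric configuration admits no unique solution (coincident or collinear points)."""


class DegenerateGeometryError(DegenerateConfigurationError):
    """Normal set / design matrix is rank deficient during registration."""


class ZeroSpreadError(JawTrackError, ValueError):
    """Grey-value distribution has no interdecile spread."""


class InsufficientDataError(JawTrackError, ValueError):
    """Too few samples to estimate the requested quantity."""


class EmptyMaskError(JawTrackError, ValueError):
    """Rasterized region contains no pixel centers."""


class OutOfRangeError(JawTrackError, ValueError):
    """Frame index outside the annotated range."""


class OutOfBoundsError(JawTrackError, ValueError):
    """Moving shape leaves the field of view."""


class MissingFileError(JawTrackError, FileNotFoundError):
    """A required input file does not exist."""


class GeometryMismatchError(JawTrackError, ValueError):
    """Image geometry and annotation disagree (frame count, spacing, shape)."""


class MalformedAnnotationError(JawTrackError, ValueError):
    """Annotation JSON is unreadable or misses required keys."""
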