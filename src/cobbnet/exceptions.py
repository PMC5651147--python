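"""Exception hierarchy shared across the pipeline.

Validation errors (bad parameters, out-of-range values, shape mismatches)
map to CLI exit code 2; data-integrity errors (corrupted containers,
truncated files) map to exit code 3.
"""


class CobbNetError(Exception):
    """Base class for all package errors."""


class ValidationError(CobbNetError, ValueError):
    """A parameter, shape, or precondition check failed."""


class DataIntegrityError(CobbNetError, IOError):
    """A file or container is corrupted, truncated, or inconsistent."""


class MarkersNotFoundError(CobbNetError):
    """Fewer than two pedicle-marker blobs were found in the window."""


class MarkerAmbiguityError(CobbNetError):
    """More than two candidate marker blobs of comparable size.

    Carries the candidate centroids for diagnostics.
    """

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class DegenerateCurveError(CobbNetError):
    """All clicked vertebrae tilt the same way; no opposite-sign pair exists.

    Raised only in strict mode; the default policy returns a flagged
    measurement instead (see :func:`cobbnet.cobb.select_end_vertebrae`).
    """

    def __init__(self, message, extreme_indices=None):
        super().__init__(message)
        self.extreme_indices = extreme_indices
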