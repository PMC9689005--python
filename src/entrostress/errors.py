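"""Exception hierarchy shared across the pipeline."""


class EntrostressError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EntrostressError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(EntrostressError, ValueError):
    """A file on disk is missing, truncated, or not in the declared format."""


class BandMissingError(EntrostressError, KeyError):
    """No cube channel lies within tolerance of a requested wavelength."""


class DegenerateImageError(EntrostressError, ValueError):
    """A range-normalized index is undefined because its global range is zero."""


class EmptyMaskError(EntrostressError, ValueError):
    """Thresholding produced a mask with no plant pixels."""
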