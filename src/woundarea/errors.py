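"""Exception hierarchy for the wound-area measurement toolkit."""


class WoundAreaError(Exception):
    """Base class for all errors raised by this package."""


class InvalidImageError(WoundAreaError):
    """Pixel data is not an 8-bit grayscale or RGB raster of the expected shape."""


class InvalidMaskError(WoundAreaError):
    """A binary mask contains values other than 0 and 255."""


class ConfigError(WoundAreaError):
    """A processing parameter is out of its admissible range."""


class DegenerateHistogramError(WoundAreaError):
    """Otsu thresholding was asked to split a single-valued histogram.

    A constant image has no foreground/background structure; callers such as
    the pipeline catch this and report "no wound detected" instead of a
    threshold chosen arbitrarily.
    """


class MissingDPIError(WoundAreaError):
    """An image file carries no physical-resolution metadata and no override was given."""


class DecodeError(WoundAreaError):
    """A file could not be decoded as PNG, JPEG or TIFF."""


class FormatError(WoundAreaError):
    """An output path has an unsupported image extension."""


class DomainError(WoundAreaError):
    """A measurement argument violates its mathematical domain (e.g. dpi <= 0)."""


class SpecError(WoundAreaError):
    """A synthetic-scene specification is geometrically invalid."""
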