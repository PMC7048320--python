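"""Exception types used across the package."""


class MixedCodesError(Exception):
    """Base class for package errors."""


class InvalidStimulusError(MixedCodesError, ValueError):
    """A stimulus has the wrong length or out-of-range feature values."""


class UnsupportedGeometryError(MixedCodesError, ValueError):
    """A receptive-field width that does not divide the number of values."""


class EmbeddingError(MixedCodesError, ValueError):
    """A linear transform was requested with fewer output than input dimensions."""


class InvalidConfigurationError(MixedCodesError, ValueError):
    """A channel or sweep configuration is internally inconsistent."""
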