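"""Exception hierarchy shared across the package."""


class RamanmixError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(RamanmixError, ValueError):
    """Array shapes are inconsistent with each other or with metadata."""


class ParameterError(RamanmixError, ValueError):
    """A configuration parameter is outside its valid domain."""


class FormatError(RamanmixError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class UndefinedAngleError(RamanmixError, ValueError):
    """Spectral angle requested for a zero-norm vector."""


class InsufficientDataError(RamanmixError, ValueError):
    """Fewer spectra than endmembers requested by a geometric extractor."""


class EmptyRangeError(RamanmixError, ValueError):
    """A spectral crop selected no bands."""


class DegenerateRangeError(RamanmixError, ValueError):
    """Min-max normalization of an all-constant dataset."""


class TrainingDivergenceError(RamanmixError, RuntimeError):
    """A non-finite loss was encountered during training."""


class ModelStateError(RamanmixError, RuntimeError):
    """Operation requires a trained/initialized model."""
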