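"""Exception hierarchy shared across the package."""


class ACNMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ACNMError):
    """Unsupported or malformed image file format."""


class DimensionalityError(ACNMError):
    """Image is not a 3D volume (or arrays disagree in shape)."""


class ValidationError(ACNMError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ACNMError):
    """Input has no usable signal (e.g. constant intensity)."""


class InitializationError(ACNMError):
    """No plausible initial brain contour could be found."""


class EmptyContourSignal(ACNMError):
    """The evolving region vanished; the caller should stop propagating."""


class DegenerateACNError(ACNMError):
    """The contour neighborhood has (near-)constant intensity (I_m <= mu)."""


class NumericalStabilityError(ACNMError):
    """The level-set update produced non-finite values."""


class ExtractionError(ACNMError):
    """Whole-volume extraction failed (e.g. middle-slice initialization)."""
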