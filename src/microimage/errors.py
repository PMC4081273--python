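"""Exception hierarchy shared across the package."""


class MicroimageError(Exception):
    """Base class for all package-specific errors."""


class ContractViolationError(MicroimageError, ValueError):
    """Sample values fall outside the declared value-range contract."""


class ShapeError(MicroimageError, ValueError):
    """Input array has the wrong dimensionality or channel count."""


class ParameterError(MicroimageError, ValueError):
    """A parameter value violates its stated constraint."""


class FormatError(MicroimageError, ValueError):
    """Malformed image file.  Carries the byte offset of the defect."""

    def __init__(self, message, offset=None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class SingularTransformError(MicroimageError, ValueError):
    """Transform matrix is singular, or a point maps to the line at infinity."""


class DegenerateGeometryError(MicroimageError, ValueError):
    """Point configuration is degenerate for the requested estimation."""


class EstimationError(MicroimageError, RuntimeError):
    """Robust estimation could not produce a model."""


class RegistrationError(MicroimageError, RuntimeError):
    """An image-registration pipeline stage failed.  Names the stage."""


class DetectionError(MicroimageError, RuntimeError):
    """An object-detection stage found nothing above threshold."""


class CapacityError(MicroimageError, RuntimeError):
    """A synthetic scene could not be populated within the retry budget."""
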