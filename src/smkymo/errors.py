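"""Exception hierarchy shared across the package."""


class SmkymoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SmkymoError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class StackFormatError(SmkymoError, ValueError):
    """A TIFF file does not form a uniform grayscale stack."""


class EmptyInputError(SmkymoError, ValueError):
    """An input contains no usable data (e.g. a zero-page TIFF)."""


class GeometryError(SmkymoError, ValueError):
    """A scan line or transform leaves the image bounds."""


class DegenerateThresholdError(SmkymoError, ValueError):
    """No meaningful intensity threshold exists (e.g. saturated kymograph)."""


class UndefinedSCIError(SmkymoError, ValueError):
    """The SCI ratio is undefined because the bottom-percentile mean is zero."""


class StageError(SmkymoError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
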