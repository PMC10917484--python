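"""Named error classes shared across the package."""


class HessDenoiseError(Exception):
    """Base class for all package-specific errors."""


class StackReadError(HessDenoiseError):
    """A stack file could not be read as a 3D grayscale TIFF."""


class MissingStackError(StackReadError, FileNotFoundError):
    """The requested stack file does not exist."""


class NonGrayscaleError(StackReadError):
    """The TIFF contains RGB/multi-sample pages; only grayscale is supported."""


class EmptyStackError(StackReadError):
    """The TIFF contains zero image pages."""


class StackWriteError(HessDenoiseError):
    """A stack could not be written to the requested location."""


class PrecisionNarrowingError(StackWriteError):
    """Writing would silently narrow binary64 data to binary32.

    Pass ``allow_narrowing=True`` to permit the (lossy) conversion.
    """


class ShapeMismatchError(HessDenoiseError):
    """Two stacks or a stack and an operator spectrum disagree in shape."""


class NonFiniteError(HessDenoiseError):
    """A NaN or Inf appeared where the algorithm requires finite values."""


class DeviceUnavailableError(HessDenoiseError):
    """The device backend was requested but no GPU array library is usable."""


class DeviceMemoryError(HessDenoiseError):
    """The device could not hold the working set; no silent CPU fallback."""
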