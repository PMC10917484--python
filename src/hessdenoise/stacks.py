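"""3D image stacks: the in-memory container plus TIFF read/write.

A stack is a real-valued intensity grid indexed ``(rows, cols, frames)``.
Frames are TIFF pages; frame numbering for reporting is 1-based, matching
how microscopists address slices in Fiji.  Working precision is IEEE-754
binary32 by default; binary64 is retained for the reference/oracle path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import (
    EmptyStackError,
    MissingStackError,
    NonFiniteError,
    NonGrayscaleError,
    PrecisionNarrowingError,
    StackWriteError,
)

#: Mapping between the IEEE-754 interchange-format names used throughout the
#: package and the numpy dtypes that store them.
PRECISION_DTYPES = {"binary32": np.dtype(np.float32), "binary64": np.dtype(np.float64)}
DTYPE_PRECISIONS = {v: k for k, v in PRECISION_DTYPES.items()}


def _as_dtype(precision: str) -> np.dtype:
    try:
        return PRECISION_DTYPES[precision]
    except KeyError:
        raise ValueError(
            f"precision must be one of {sorted(PRECISION_DTYPES)}, got {precision!r}"
        ) from None


@dataclass(frozen=True)
class ImageStack:
    """A finite 3D intensity grid with a declared floating-point precision.

    Parameters
    ----------
    data
        3D array shaped ``(rows, cols, frames)``.  Must be float32 or
        float64 and contain no NaN/Inf.
    """

    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"stack data must be 3D, got {arr.ndim}D")
        if any(n < 1 for n in arr.shape):
            raise ValueError(f"every dimension must have length >= 1, got {arr.shape}")
        if arr.dtype not in DTYPE_PRECISIONS:
            raise ValueError(f"stack dtype must be float32/float64, got {arr.dtype}")
        if not np.isfinite(arr).all():
            raise NonFiniteError("stack contains NaN or Inf values")
        object.__setattr__(self, "data", arr)

    @property
    def precision(self) -> str:
        """Declared precision, ``"binary32"`` or ``"binary64"``."""
        return DTYPE_PRECISIONS[self.data.dtype]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(rows, cols, frames)."""
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def frame(self, index: int) -> np.ndarray:
        """Return one frame by its 1-based index (frame 1 = TIFF page 1)."""
        if not 1 <= index <= self.n_frames:
            raise IndexError(
                f"frame {index} out of range 1..{self.n_frames} (frames are 1-based)"
            )
        return self.data[:, :, index - 1]


def as_precision(stack: ImageStack, precision: str) -> ImageStack:
    """Round every element to nearest at the target precision.

    Idempotent; the input stack is left untouched.  Values that are exactly
    representable at the target precision (e.g. small integers) survive
    unchanged; others pick up the usual representation error — the decimal
    0.3 becomes 0.300000011920928955078125 in binary32.
    """
    dtype = _as_dtype(precision)
    if stack.data.dtype == dtype:
        return stack
    return ImageStack(stack.data.astype(dtype))


def read_stack(path: str | os.PathLike, precision: str = "binary32") -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    Pages become frames (page 1 -> frame 1); 8/16-bit integer pixels are
    promoted to the requested float precision (default binary32).
    """
    dtype = _as_dtype(precision)
    path = Path(path)
    if not path.exists():
        raise MissingStackError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise EmptyStackError(f"TIFF contains no image pages: {path}")
        spp = tif.pages[0].samplesperpixel
        if spp != 1:
            raise NonGrayscaleError(
                f"TIFF pages have {spp} samples per pixel (RGB?): {path}"
            )
        arr = tif.asarray()
    if arr.ndim == 2:  # single page
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise NonGrayscaleError(
            f"expected grayscale pages, got array of shape {arr.shape} from {path}"
        )
    data = np.moveaxis(arr, 0, -1).astype(dtype)
    return ImageStack(data)


def write_stack(
    stack: ImageStack,
    path: str | os.PathLike,
    precision: str | None = None,
    allow_narrowing: bool = False,
) -> None:
    """Write a stack as a multi-page float TIFF, bit-faithful at ``precision``.

    ``read_stack(write_stack(s))`` is the identity on values at the declared
    precision.  Narrowing binary64 data to binary32 loses bits and must be
    requested explicitly via ``allow_narrowing``.
    """
    precision = precision or stack.precision
    dtype = _as_dtype(precision)
    if stack.data.dtype == np.float64 and dtype == np.float32 and not allow_narrowing:
        raise PrecisionNarrowingError(
            "writing a binary64 stack as binary32 narrows precision; "
            "pass allow_narrowing=True to permit it"
        )
    path = Path(path)
    pages = np.moveaxis(stack.data.astype(dtype), -1, 0)
    try:
        tifffile.imwrite(path, pages, photometric="minisblack")
    except (OSError, PermissionError) as exc:
        raise StackWriteError(f"cannot write stack to {path}: {exc}") from exc
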