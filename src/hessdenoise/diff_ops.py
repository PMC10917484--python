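"""First- and second-order finite differences on 3D grids.

All operators are shape-preserving: the adjacent-element difference loses one
slice along its axis, and that slice is refilled with zeros (forward
differences zero the LAST slice, backward differences the FIRST).  This
zero-fill convention makes every operator an exactly representable square
linear map, so the adjoint (matrix transpose) is available in closed form —
a requirement of the split-Bregman image update.

Each operator exists in two numerically identical implementations:

* ``naive``      — builds two shifted temporary copies and subtracts them,
  mirroring how straightforward hand-written difference code is usually
  structured;
* ``vectorized`` — writes strided slice differences directly into a
  preallocated output array.

Both produce bit-identical results at the same precision; only memory
traffic differs.  Optional :class:`CallCounters` instrumentation records how
often the operators run (24 first-difference calls and 6 shrinkage passes
per denoiser iteration on the reference path).
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

_VALID_DIMS = (1, 2, 3)


class Direction(Enum):
    """The six independent second-derivative directions of a 3D Hessian."""

    XX = ("xx", (1, 1))
    XY = ("xy", (1, 2))
    XZ = ("xz", (1, 3))
    YY = ("yy", (2, 2))
    YZ = ("yz", (2, 3))
    ZZ = ("zz", (3, 3))

    def __init__(self, label: str, dims: tuple[int, int]):
        self.label = label
        self.dims = dims

    @property
    def is_diagonal(self) -> bool:
        return self.dims[0] == self.dims[1]

    @classmethod
    def from_label(cls, label: str) -> "Direction":
        for d in cls:
            if d.label == label:
                return d
        raise ValueError(f"unknown direction {label!r}; expected one of "
                         f"{[d.label for d in cls]}")


#: Fixed processing order for the six directional tasks.  Reductions over
#: directions always follow this order so results are deterministic even
#: when the tasks execute concurrently.
DIRECTIONS: tuple[Direction, ...] = (
    Direction.XX, Direction.XY, Direction.XZ,
    Direction.YY, Direction.YZ, Direction.ZZ,
)


@dataclass
class CallCounters:
    """Monotone counters of operator invocations during a denoising run.

    Increments go through a lock so counts stay exact when the six
    directional tasks run on concurrent threads.
    """

    forward_calls: int = 0
    backward_calls: int = 0
    shrink_executions: int = 0
    iterations_completed: int = 0
    _lock: threading.Lock = field(
        default_factory=threading.Lock, repr=False, compare=False
    )

    def incr(self, name: str, n: int = 1) -> None:
        with self._lock:
            setattr(self, name, getattr(self, name) + n)

    def as_dict(self) -> dict[str, int]:
        return {
            "forward_calls": self.forward_calls,
            "backward_calls": self.backward_calls,
            "shrink_executions": self.shrink_executions,
            "iterations_completed": self.iterations_completed,
        }


def _axis(dim: int) -> int:
    if dim not in _VALID_DIMS:
        raise ValueError(f"dim must be in {_VALID_DIMS}, got {dim}")
    return dim - 1


def _sl(axis: int, s: slice) -> tuple[slice, ...]:
    idx = [slice(None)] * 3
    idx[axis] = s
    return tuple(idx)


def forward_diff(
    a: np.ndarray,
    dim: int,
    out: np.ndarray | None = None,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """out[i] = a[i+1] - a[i] along ``dim`` (1-based); last slice zero-filled.

    A size-1 dimension yields all zeros.  The same shape as ``a`` is always
    returned, so compositions never need shape bookkeeping.
    """
    ax = _axis(dim)
    if counters is not None:
        counters.incr("forward_calls")
    if naive:
        # Two full-size temporaries holding shifted copies, then one subtract.
        left = np.zeros_like(a)
        right = np.zeros_like(a)
        left[_sl(ax, slice(None, -1))] = a[_sl(ax, slice(1, None))]
        right[_sl(ax, slice(None, -1))] = a[_sl(ax, slice(None, -1))]
        result = left - right
        if out is not None:
            out[...] = result
            return out
        return result
    if out is None:
        out = np.empty_like(a)
    np.subtract(
        a[_sl(ax, slice(1, None))], a[_sl(ax, slice(None, -1))],
        out=out[_sl(ax, slice(None, -1))],
    )
    out[_sl(ax, slice(-1, None))] = 0
    return out


def back_diff(
    a: np.ndarray,
    dim: int,
    out: np.ndarray | None = None,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """out[i] = a[i] - a[i-1] along ``dim`` (1-based); first slice zero-filled."""
    ax = _axis(dim)
    if counters is not None:
        counters.incr("backward_calls")
    if naive:
        left = np.zeros_like(a)
        right = np.zeros_like(a)
        left[_sl(ax, slice(1, None))] = a[_sl(ax, slice(1, None))]
        right[_sl(ax, slice(1, None))] = a[_sl(ax, slice(None, -1))]
        result = left - right
        if out is not None:
            out[...] = result
            return out
        return result
    if out is None:
        out = np.empty_like(a)
    np.subtract(
        a[_sl(ax, slice(1, None))], a[_sl(ax, slice(None, -1))],
        out=out[_sl(ax, slice(1, None))],
    )
    out[_sl(ax, slice(None, 1))] = 0
    return out


def adjoint_forward_diff(
    a: np.ndarray,
    dim: int,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """Exact matrix transpose of :func:`forward_diff` under zero-fill.

    Because forward_diff zeroes (never reads into) its last output slice,
    the transpose ignores the last input slice and spills one boundary term
    into each end:  out[0] = -a[0], out[j] = a[j-1] - a[j], out[n-1] = a[n-2].
    """
    ax = _axis(dim)
    if counters is not None:
        counters.incr("forward_calls")
    z = a.copy() if naive else np.array(a, copy=True)
    z[_sl(ax, slice(-1, None))] = 0
    shifted = np.zeros_like(z)
    shifted[_sl(ax, slice(1, None))] = z[_sl(ax, slice(None, -1))]
    return shifted - z


def adjoint_back_diff(
    a: np.ndarray,
    dim: int,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """Exact matrix transpose of :func:`back_diff` under zero-fill."""
    ax = _axis(dim)
    if counters is not None:
        counters.incr("backward_calls")
    z = a.copy() if naive else np.array(a, copy=True)
    z[_sl(ax, slice(None, 1))] = 0
    shifted = np.zeros_like(z)
    shifted[_sl(ax, slice(None, -1))] = z[_sl(ax, slice(1, None))]
    return z - shifted


def second_diff(
    a: np.ndarray,
    d: Direction,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """Second difference for one Hessian direction.

    Diagonal directions (xx, yy, zz) compose backward after forward along
    the same axis, giving the classic [1, -2, 1] interior stencil.  Cross
    directions (xy, xz, yz) compose two forward differences along the two
    distinct axes, which keeps the operator symmetric in its axes.
    """
    k, l = d.dims
    if d.is_diagonal:
        return back_diff(forward_diff(a, k, counters=counters, naive=naive),
                         k, counters=counters, naive=naive)
    return forward_diff(forward_diff(a, k, counters=counters, naive=naive),
                        l, counters=counters, naive=naive)


def adjoint_second_diff(
    a: np.ndarray,
    d: Direction,
    counters: CallCounters | None = None,
    naive: bool = False,
) -> np.ndarray:
    """Exact matrix transpose of :func:`second_diff`: (B A)^T = A^T B^T."""
    k, l = d.dims
    if d.is_diagonal:
        return adjoint_forward_diff(
            adjoint_back_diff(a, k, counters=counters, naive=naive),
            k, counters=counters, naive=naive,
        )
    return adjoint_forward_diff(
        adjoint_forward_diff(a, l, counters=counters, naive=naive),
        k, counters=counters, naive=naive,
    )
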