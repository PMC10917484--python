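"""Execution backends: serial CPU, six-thread CPU, and GPU-style device.

The denoiser is written against the numpy API; a backend supplies the array
namespace, the FFT pair, and the host<->device transfer functions.  The
device backend follows the one-transfer-in / one-gather-out discipline: all
working arrays are moved to device memory before the iteration loop and
results are copied back exactly once after it, so no per-iteration
host-device traffic occurs.  Timing a device run must bracket the gather,
since device execution is asynchronous until results are fetched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
import scipy.fft

from .exceptions import DeviceMemoryError, DeviceUnavailableError

#: The six directional tasks are independent within one iteration, so the
#: parallel CPU backend uses exactly six workers.
N_TASK_WORKERS = 6

BACKENDS = ("cpu_serial", "cpu_parallel", "device")


@dataclass(frozen=True)
class Backend:
    name: str
    xp: Any
    fftn: Callable
    ifftn: Callable
    to_device: Callable[[np.ndarray], Any]
    gather: Callable[[Any], np.ndarray]
    n_workers: int  # 0 = serial


def _cpu(name: str, n_workers: int) -> Backend:
    return Backend(
        name=name,
        xp=np,
        fftn=scipy.fft.fftn,
        ifftn=scipy.fft.ifftn,
        to_device=lambda a: a,
        gather=lambda a: a,
        n_workers=n_workers,
    )


def _device() -> Backend:
    try:
        import cupy  # noqa: PLC0415 — optional GPU dependency
        import cupyx.scipy.fft as cufft  # noqa: PLC0415
    except ImportError as exc:
        raise DeviceUnavailableError(
            "backend 'device' requires a CUDA-capable GPU with cupy installed"
        ) from exc
    try:
        cupy.cuda.runtime.getDeviceCount()
    except Exception as exc:
        raise DeviceUnavailableError(f"no usable CUDA device: {exc}") from exc

    def to_device(a: np.ndarray):
        try:
            return cupy.asarray(a)
        except cupy.cuda.memory.OutOfMemoryError as exc:
            raise DeviceMemoryError(
                f"device memory exhausted transferring array of shape {a.shape}"
            ) from exc

    return Backend(
        name="device",
        xp=cupy,
        fftn=cufft.fftn,
        ifftn=cufft.ifftn,
        to_device=to_device,
        # gather synchronizes: it waits for all queued device work, then
        # copies the result back to host memory.
        gather=lambda a: cupy.asnumpy(a),
        n_workers=0,
    )


def resolve_backend(name: str, fallback: bool = False) -> Backend:
    """Return the named backend.

    With ``fallback=True`` an unavailable device degrades to cpu_serial
    instead of raising; by default the capability error propagates so a
    missing GPU is never silently papered over.
    """
    if name == "cpu_serial":
        return _cpu(name, 0)
    if name == "cpu_parallel":
        return _cpu(name, N_TASK_WORKERS)
    if name == "device":
        try:
            return _device()
        except DeviceUnavailableError:
            if fallback:
                return _cpu("cpu_serial", 0)
            raise
    raise ValueError(f"unknown backend {name!r}; expected one of {BACKENDS}")
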