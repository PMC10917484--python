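"""Fourier-domain denominator of the split-Bregman image update.

The quadratic image solve inverts ``mu + lam * sum_d w_d^2 |H_d(k)|^2``
pointwise in frequency space, where ``H_d`` is the periodic (circulant)
transfer function of the second-difference operator for direction ``d``.
For a 1D second difference the squared modulus is ``(2 - 2 cos(2 pi k/n))``
per participating axis, so each direction contributes the product of its two
axis factors.

Because the spectrum depends only on the stack shape, the axial weight sigma
and the per-direction weights, it is computed once and persisted on disk,
keyed by shape (e.g. ``128-256-180.npz``), and simply reloaded on later runs
with the same geometry.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diff_ops import DIRECTIONS, Direction

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1

#: Default sigma -> per-direction weight mapping.  In-plane curvature gets
#: unit weight, the doubled off-diagonal Hessian entries get weight 2, and
#: directions involving the axial (z) dimension are scaled by sigma (cross
#: terms) or sigma^2 (pure zz), expressing that axial continuity is
#: penalized relative to lateral continuity.
def direction_weights(sigma: float, overrides: dict[str, float] | None = None) -> dict[str, float]:
    """Per-direction weights w_d for a given axial weight sigma."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    w = {
        "xx": 1.0,
        "yy": 1.0,
        "xy": 2.0,
        "xz": 2.0 * sigma,
        "yz": 2.0 * sigma,
        "zz": sigma * sigma,
    }
    if overrides:
        unknown = set(overrides) - set(w)
        if unknown:
            raise ValueError(f"unknown direction labels in weight overrides: {unknown}")
        w.update(overrides)
    return w


@dataclass(frozen=True)
class OperatorSpectrum:
    """Precomputed frequency response sum_d w_d^2 |H_d(k)|^2 for one shape."""

    shape: tuple[int, int, int]
    sigma: float
    weights: dict[str, float]
    values: np.ndarray = field(repr=False)

    def weight(self, d: Direction) -> float:
        return self.weights[d.label]


def _axis_factor(n: int, dtype=np.float64) -> np.ndarray:
    """|DFT of the periodic first-difference kernel|^2 = 2 - 2 cos(2 pi k / n)."""
    k = np.arange(n, dtype=dtype)
    return 2.0 - 2.0 * np.cos(2.0 * np.pi * k / n)


def build_spectrum(
    shape: tuple[int, int, int],
    sigma: float,
    weights: dict[str, float] | None = None,
) -> OperatorSpectrum:
    """Evaluate the composite operator spectrum on the frequency lattice.

    Deterministic: identical inputs give bit-identical values.  The result
    is non-negative everywhere and exactly zero at DC (second differences
    annihilate constants), which is what preserves the image mean through
    every split-Bregman iteration.
    """
    if len(shape) != 3 or any(n < 1 for n in shape):
        raise ValueError(f"shape must be three positive dimensions, got {shape}")
    w = weights if weights is not None else direction_weights(sigma)
    factors = [_axis_factor(n) for n in shape]
    values = np.zeros(shape, dtype=np.float64)
    for d in DIRECTIONS:
        k, l = d.dims
        fk = factors[k - 1].reshape([-1 if ax == k - 1 else 1 for ax in range(3)])
        fl = factors[l - 1].reshape([-1 if ax == l - 1 else 1 for ax in range(3)])
        values += (w[d.label] ** 2) * (fk * fl)
    return OperatorSpectrum(shape=tuple(shape), sigma=float(sigma), weights=dict(w),
                            values=values)


def cache_key(shape: tuple[int, int, int]) -> str:
    """Shape-keyed cache basename, e.g. (128, 256, 180) -> "128-256-180"."""
    return "-".join(str(int(n)) for n in shape)


def _cache_path(cache_dir: str | os.PathLike, shape) -> Path:
    return Path(cache_dir) / f"{cache_key(shape)}.npz"


def save_spectrum(spec: OperatorSpectrum, cache_dir: str | os.PathLike) -> Path:
    """Persist a spectrum under ``cache_dir`` in a self-describing container."""
    path = _cache_path(cache_dir, spec.shape)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = sorted(spec.weights)
    np.savez(
        path,
        format_version=np.int64(_FORMAT_VERSION),
        shape=np.asarray(spec.shape, dtype=np.int64),
        sigma=np.float64(spec.sigma),
        weight_labels=np.asarray(labels),
        weight_values=np.asarray([spec.weights[k] for k in labels], dtype=np.float64),
        values=spec.values,
    )
    return path


def load_or_build(
    shape: tuple[int, int, int],
    sigma: float,
    weights: dict[str, float] | None = None,
    cache_dir: str | os.PathLike = ".",
) -> OperatorSpectrum:
    """Return the spectrum for ``shape``, reusing an on-disk copy when valid.

    A cache hit must match shape, sigma, weights and format version exactly;
    anything else (including a corrupt or truncated file) triggers a silent
    rebuild-and-overwrite with a logged warning, so a damaged cache can never
    change numerical results.
    """
    w = weights if weights is not None else direction_weights(sigma)
    path = _cache_path(cache_dir, shape)
    if path.exists():
        try:
            with np.load(path, allow_pickle=False) as payload:
                ok = (
                    int(payload["format_version"]) == _FORMAT_VERSION
                    and tuple(payload["shape"]) == tuple(shape)
                    and float(payload["sigma"]) == float(sigma)
                    and list(payload["weight_labels"]) == sorted(w)
                    and np.array_equal(
                        payload["weight_values"],
                        np.asarray([w[k] for k in sorted(w)], dtype=np.float64),
                    )
                )
                if ok:
                    return OperatorSpectrum(
                        shape=tuple(shape), sigma=float(sigma), weights=dict(w),
                        values=payload["values"],
                    )
                logger.warning(
                    "spectrum cache %s is stale (parameters changed); rebuilding", path
                )
        except Exception as exc:  # corrupt/truncated/foreign file
            logger.warning("spectrum cache %s unreadable (%s); rebuilding", path, exc)
    spec = build_spectrum(shape, sigma, w)
    save_spectrum(spec, cache_dir)
    return spec
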