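"""Synthetic 3D fluorescence phantoms: filaments, blur, Gaussian+Poisson noise.

Emulates the kind of data the denoiser targets — a multi-frame stack of
smooth bright curvilinear structures on a dark background, as produced by
structured illumination microscopy of cytoskeletal filaments.  The clean
volume is a set of random 3D polylines rasterized at ``filament_intensity``,
blurred by an isotropic Gaussian point-spread proxy, on a constant
background.  The noisy companion adds shot noise (Poisson, parameterized by
``photon_scale`` photons per intensity unit) and additive Gaussian camera
noise.

Everything is driven by one explicit ``numpy.random.default_rng(seed)``
generator: the same spec always yields byte-identical stacks, and no global
RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stacks import PRECISION_DTYPES, ImageStack


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic filament stack.

    Defaults produce a full-size stack of the geometry the denoiser is
    typically run on (128 rows x 256 cols x 180 frames); tests scale the
    shape down.  Intensities are in [0, ~1] arbitrary camera units.
    """

    shape: tuple[int, int, int] = (128, 256, 180)
    n_filaments: int = 12
    filament_intensity: float = 1.0
    background: float = 0.05
    psf_sigma: float = 1.2
    gaussian_noise_sd: float = 0.1
    poisson: bool = False
    photon_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.background < 0 or self.filament_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")


def _rasterize_filaments(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw random 3D polylines by dense sampling along their segments."""
    shape = np.asarray(spec.shape, dtype=np.float64)
    vol = np.zeros(spec.shape, dtype=np.float64)
    n_segments = 6
    for _ in range(spec.n_filaments):
        pos = rng.uniform(0, shape - 1)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_segments):
            # gentle random turn keeps the filament smooth and continuous
            turn = rng.normal(scale=0.35, size=3)
            direction = direction + turn
            direction /= np.linalg.norm(direction)
            seg_len = rng.uniform(0.15, 0.45) * float(shape.min())
            n_steps = max(int(seg_len * 2), 2)
            for step in range(n_steps):
                p = pos + direction * (seg_len * step / n_steps)
                idx = np.round(p).astype(int)
                if np.all(idx >= 0) and np.all(idx < spec.shape):
                    vol[tuple(idx)] = spec.filament_intensity
            pos = pos + direction * seg_len
    return vol


def make_phantom(
    spec: PhantomSpec, precision: str = "binary32"
) -> tuple[ImageStack, ImageStack]:
    """Return a (clean, noisy) stack pair fully determined by ``spec.seed``.

    clean = background + Gaussian-blurred filaments.
    noisy = clean + N(0, gaussian_noise_sd); with ``poisson`` enabled the
    signal term is first replaced by Poisson(photon_scale * clean) /
    photon_scale, modelling shot noise at the given photon budget.
    """
    rng = np.random.default_rng(spec.seed)
    vol = _rasterize_filaments(spec, rng)
    if spec.psf_sigma > 0:
        vol = gaussian_filter(vol, sigma=spec.psf_sigma, mode="constant")
    clean = spec.background + vol

    signal = clean
    if spec.poisson:
        signal = rng.poisson(spec.photon_scale * clean) / spec.photon_scale
    noise = (
        rng.normal(0.0, spec.gaussian_noise_sd, size=spec.shape)
        if spec.gaussian_noise_sd > 0
        else 0.0
    )
    noisy = signal + noise

    dtype = PRECISION_DTYPES[precision]
    return (
        ImageStack(clean.astype(dtype)),
        ImageStack(np.asarray(noisy, dtype=dtype).reshape(spec.shape)),
    )
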