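# Methods

## Model

Given a noisy grayscale stack `f ∈ R^{n1×n2×n3}` (rows × columns ×
frames), the denoised stack `u` minimizes

```
(μ/2)·‖u − f‖₂²  +  Σ_d w_d·‖D_d u‖₁ ,   d ∈ {xx, xy, xz, yy, yz, zz}
```

`D_d` are discrete second differences built from first differences with
a zero-fill boundary convention: the forward difference zeroes its last
slice along the working axis, the backward difference zeroes its first
slice. Pure directions (`xx`, `yy`, `zz`) compose a backward after a
forward difference along one axis; cross directions (`xy`, `xz`, `yz`)
compose two forward differences along distinct axes. Adjoints are exact
matrix transposes of these operators (verified against materialized
matrices in the test suite), so `⟨D x, y⟩ = ⟨x, Dᵀ y⟩` holds to the
limits of floating point.

The split-Bregman iteration carries auxiliary variables `d_d` and
Bregman variables `b_d` per direction. One iteration:

1. Per direction (six independent tasks):
   `s_d = D_d u + b_d`; `d_d ← shrink(s_d, w_d/λ)`; `b_d ← s_d − d_d`;
   `c_d = w_d · D_dᵀ(d_d − b_d)`, where
   `shrink(v, t) = sign(v)·max(|v| − t, 0)`.
2. Image update in Fourier space:
   `u ← Re(IFFT( FFT(μf + λ·Σ_d c_d) / (μ + λ·S) ))`, with the
   operator spectrum `S(k) = Σ_d w_d² · Π_{a ∈ dims(d)} (2 − 2cos(2πk_a/n_a))`.

`S` is zero at DC, so the update preserves the stack mean exactly up to
rounding (measured drift ~1e-17 in binary64). `S` is real, non-negative
and conjugate-symmetric; it depends only on the shape, σ and the
weights, so the optimized path persists it as an `.npz` file keyed by
shape (`"128-256-180.npz"`), with the format version, σ and weights
stored and verified on load — a stale or corrupt file triggers a logged
rebuild, never a wrong answer.

## Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| `mu` (fidelity) | 10.0 | Geometric center of the working range (2, 50): below ~2 the result oversmooths toward the mean; above ~50 little noise is removed. Validated but not clamped. |
| `sigma` (axial weight) | 1.0 | Treats z like x/y; σ<1 de-emphasizes the axial Hessian for anisotropic PSFs. |
| weights | `(1, 2, 2σ, 1, 2σ, σ²)` for `(xx, xy, xz, yy, yz, zz)` | Off-diagonal terms count twice (Hessian symmetry); each z index contributes one factor of σ. Overridable per direction. |
| `bregman_lambda` | 1.0 | Standard split-Bregman coupling; thresholds become `w_d/λ`. |
| `iterations` | 100 | Fixed count rather than a convergence test, so reference and optimized runs are structurally identical; diagnostics (objective, max step) are available via `track_diagnostics`. |
| `precision` | reference: binary64; optimized: binary32 | The reference is the numerical ground truth; the optimized default trades 7 decimal digits for half the memory traffic. |
| binary32 tolerance | max relative error ≤ 1e-4 | Contract for the precision-reduced path; measured agreement is ~3e-7 after 100 iterations, so the bound has ~3 orders of margin and is not tuned to pass. |

Uniform precision is enforced throughout an iteration: `scipy.fft` is
used (not `numpy.fft`) because it maps float32 → complex64 and keeps
the binary32 path genuinely single-precision end to end.

## Reference vs optimized paths

Both paths execute the same arithmetic expressions in the same order;
the optimized path changes only structure:

- vectorized slice-wise differences writing into preallocated buffers
  (vs naive shifted temporaries) — identical values by construction;
- shared first-difference buffers across the six directions
  (de-duplication) — reuses results, never recomputes them differently;
- spectrum loaded from the cache — bit-identical to a fresh build;
- six-task thread pool with a fixed direction-order reduction of
  `Σ c_d`, so the sum is associativity-stable regardless of completion
  order.

Consequently in binary64 on CPU the two paths are byte-identical
(asserted in tests and recomputed by `scripts/acceptance.py`). The
`device` backend mirrors the CPU code through an array-namespace
abstraction with one host→device transfer before the loop and one
gather after; it requires cupy and fails loudly
(`DeviceUnavailableError`, CLI exit 3) when unavailable, with an
explicit opt-in `fallback` to `cpu_serial`.

Per iteration the reference path performs 24 first-difference calls
(6 directions × 2 calls in `D_d` + 2 in `D_dᵀ`) and 6 shrinkage
passes, counted thread-safely by `CallCounters`.

## Synthetic phantom

`make_phantom` draws random 3D polylines ("filaments", 6 segments each,
gentle turning angles), rasterizes them at unit intensity over a
constant background (0.05), blurs with an isotropic Gaussian PSF
(σ = 1.2 voxels) as a stand-in for the microscope's point-spread
function, and adds Gaussian read noise (SD 0.1) and optionally Poisson
shot noise at a configurable photon scale. It emulates the *statistics*
relevant to the denoiser — curvilinear structures, band-limited blur,
mixed noise — not the optics of any particular instrument: there is no
structured-illumination pattern, no depth-varying or anisotropic PSF,
and no camera offset/gain model. All randomness flows from one
`numpy.random.default_rng(seed)`.

## Numerical choices and limitations

- The spectrum uses the periodic (DFT) magnitude of each stencil while
  the spatial operators use zero-fill boundaries; the mismatch affects
  only a boundary layer a few voxels thick and is the standard
  trade-off for an FFT-diagonalized update. Interior behavior and mean
  preservation are unaffected.
- `shrink` uses `sign`, so `shrink(−0.0, t)` returns `−0.0`; the
  straight-line oracle in the tests matches this exactly.
- Quality metrics follow per-frame SNR/PSNR/RMSE/MAE conventions with
  mean ± SD aggregation over frames; identical stacks yield SNR = +inf,
  serialized as the string `"inf"`; all-zero reference frames yield
  `"undefined"` and are excluded from the SNR aggregate.
- `float_repr` expands a decimal literal's nearest binary32/binary64
  value to its exact decimal digits (e.g. 0.3 → 24 fractional digits in
  binary32, 54 in binary64), useful when reasoning about byte-level
  diffs between precisions.
- Problem sizes in the tests (12³–64³-scale stacks, 8–100 iterations)
  are chosen so the full suite runs in seconds; the default phantom
  geometry 128×256×180 exercises the cache key and shape facts without
  being iterated at full size.
- Fixed iteration counts mean no early stopping; μ is the only
  data-fidelity control and must be chosen by the user (the working
  range (2, 50) is a guideline, not enforced).
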