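# hessdenoise

Hessian-regularized denoising of 3D fluorescence-microscopy stacks
(structured-illumination style data), with a naive reference
implementation and a structurally optimized implementation that is
**bit-identical** to it in double precision.

## The problem

Live-cell super-resolution stacks are photon-starved: raw frames carry
strong Gaussian/Poisson noise, and biological structures (filaments,
membranes) are smooth along their length. A well-suited prior penalizes
the image's second derivatives. Given a noisy stack `f`, we solve

```
min_u  (μ/2)·‖u − f‖²  +  Σ_d w_d·‖D_d u‖₁
```

where `d` ranges over the six 3D Hessian directions
`{xx, xy, xz, yy, yz, zz}`, `D_d` are finite-difference second
derivatives, and the weights `w = (1, 2, 2σ, 1, 2σ, σ²)` control how
strongly the axial (z) dimension participates. The split-Bregman scheme
alternates six independent per-direction shrinkage tasks with one
FFT-based image update whose denominator — the operator spectrum
`Σ_d w_d²·|DFT(stencil_d)|²` — depends only on the stack geometry and is
therefore precomputed and cached on disk.

The package is aimed at people who maintain or port this kind of
iterative reconstruction code and need to verify that a rewrite
(vectorization, de-duplication, multithreading, reduced precision, GPU
arrays) is *numerically faithful*, not just visually similar.

## What's inside

| Area | API |
|---|---|
| Stack I/O | `ImageStack`, `read_stack`, `write_stack` |
| Difference operators | `forward_diff`, `back_diff`, `second_diff`, adjoints, `CallCounters` |
| Operator spectrum | `build_spectrum`, `load_or_build`, `cache_key`, `direction_weights` |
| Denoisers | `denoise_reference`, `denoise_optimized`, `DenoiseParams`, `shrink` |
| Synthetic data | `PhantomSpec`, `make_phantom` |
| Comparison | `quality`, `byte_compare`, `line_profile`, `float_repr` |
| Benchmark | `StageSpec`, `run_benchmark`, `format_table` |
| CLI | `hessdenoise phantom / denoise / bench / compare / float-repr` |

Both denoisers route through the same per-task arithmetic; the
optimized path only changes *structure* (preallocated buffers, shared
first differences, cached spectrum, thread pool with fixed-order
reduction), so in binary64 on CPU its output is byte-for-byte equal to
the reference. In binary32 the paths agree to a maximum relative error
below 1e-4 (measured: ~3e-7).

## Worked example

`examples/denoise_phantom.py` builds a 64×64×32 filament phantom with
Gaussian noise of SD 0.1 and denoises it (μ=10, σ=1, 40 iterations):

```
RMSE vs clean, noisy input : 0.099902
RMSE vs clean, denoised    : 0.010193
SNR of noisy input  : -5.38 dB
SNR after denoising : 14.57 dB
iterations completed: 40
```

`examples/equivalence_check.py` verifies the optimization contract:

```
binary64: differing bytes = 0 of 16384 (bit-identical: True)
binary32: differing bytes = 1515, byte-position histogram within 4-byte words = (1503, 12, 0, 0)
binary32 max relative error vs binary64 reference = 2.675e-07 (tolerance 1e-4)
```

The histogram shows that binary32 byte differences sit almost entirely
in the lowest-order byte of each 4-byte float — rounding noise, not
structural divergence. The other examples demonstrate the spectrum
cache (`examples/spectrum_cache.py`) and the optimization-stage
benchmark (`examples/benchmark_stages.py`).

The same things are available from the shell:

```bash
hessdenoise phantom --shape 64 64 32 --gaussian-noise-sd 0.1 --seed 12 \
    --output noisy.tif --output-clean clean.tif
hessdenoise denoise --input noisy.tif --output out.tif --mu 10 --iters 40 --impl optimized
hessdenoise compare --mode quality --ref clean.tif --test out.tif
```

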