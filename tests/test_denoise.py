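"""Denoiser: shrinkage, single iterations vs the straight-line oracle,
reference/optimized equivalence, counters, and parameter behavior."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hessdenoise import (
    DIRECTIONS,
    CallCounters,
    DenoiseParams,
    ImageStack,
    PhantomSpec,
    SplitState,
    build_spectrum,
    denoise_optimized,
    denoise_reference,
    iterate_once,
    make_phantom,
    shrink,
)
from hessdenoise.exceptions import DeviceUnavailableError, ShapeMismatchError
from oracles import straight_line_iteration


class TestShrink:
    def test_closed_forms(self):
        assert shrink(np.array(0.0), 5.0) == 0.0
        np.testing.assert_array_equal(
            shrink(np.array([-1.0, 2.0]), 0.0), [-1.0, 2.0]
        )
        assert shrink(np.array(3.0), 1.0) == 2.0
        assert shrink(np.array(-3.0), 1.0) == -2.0

    def test_inner_truncation_matches_logical_index_zeroing(self):
        signd = np.array([-1.0, 2.0, -0.5, 3.0])
        truncated = np.maximum(signd, 0)  # the max-with-zero rewrite
        by_indexing = signd.copy()
        by_indexing[by_indexing < 0] = 0
        np.testing.assert_array_equal(truncated, by_indexing)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(np.zeros(3), -0.1)

    @given(
        v=arrays(np.float64, shape=(3, 3, 2),
                 elements=st.floats(-50, 50, allow_nan=False)),
        t=st.floats(0, 10),
    )
    def test_nonexpansive(self, v, t):
        assert np.all(np.abs(shrink(v, t)) <= np.abs(v))

    def test_counts_one_execution_per_call(self):
        c = CallCounters()
        shrink(np.zeros(4), 1.0, counters=c)
        shrink(np.zeros(4), 1.0, counters=c)
        assert c.shrink_executions == 2


def _fresh(shape, params, rng=None, dtype=np.float64):
    f = (rng.normal(size=shape) if rng is not None else np.zeros(shape)).astype(dtype)
    spectrum = build_spectrum(shape, params.sigma, params.resolved_weights())
    state = SplitState.zeros(shape, dtype)
    return f, spectrum, state


class TestIterateOnce:
    def test_constant_input_is_fixed_point(self):
        params = DenoiseParams(mu=5.0)
        shape = (6, 5, 4)
        f = np.full(shape, 2.5)
        spectrum = build_spectrum(shape, params.sigma, params.resolved_weights())
        state = SplitState.zeros(shape, np.float64)
        u_new, state = iterate_once(f.copy(), f, state, spectrum, params)
        # constants have only DC content and the spectrum is zero at DC
        np.testing.assert_allclose(u_new, f, rtol=0, atol=1e-13)
        for d in DIRECTIONS:
            assert np.all(state.d[d] == 0)
            assert np.all(state.b[d] == 0)

    def test_matches_straight_line_oracle_bit_exactly(self, rng):
        params = DenoiseParams(mu=7.0, sigma=0.9)
        shape = (4, 4, 4)
        f, spectrum, state = _fresh(shape, params, rng)
        u = rng.normal(size=shape)
        b0 = {d.label: rng.normal(size=shape) for d in DIRECTIONS}
        for d in DIRECTIONS:
            state.b[d] = b0[d.label].copy()

        u_pkg, state = iterate_once(u.copy(), f, state, spectrum, params)
        u_orc, d_orc, b_orc = straight_line_iteration(
            u.copy(), f, b0, params.mu, params.bregman_lambda,
            params.resolved_weights(), spectrum.values,
            [(d.label, d.dims) for d in DIRECTIONS],
        )
        assert u_pkg.tobytes() == u_orc.tobytes()
        for d in DIRECTIONS:
            assert state.d[d].tobytes() == d_orc[d.label].tobytes()
            assert state.b[d].tobytes() == b_orc[d.label].tobytes()

    def test_counter_arithmetic_per_iteration(self, rng):
        params = DenoiseParams()
        shape = (5, 4, 3)
        f, spectrum, state = _fresh(shape, params, rng)
        c = CallCounters()
        iterate_once(f.copy(), f, state, spectrum, params,
                     counters=c, naive=True, dedup=False)
        assert c.forward_calls + c.backward_calls == 24
        assert c.shrink_executions == 6

    def test_spectrum_shape_mismatch_rejected(self, rng):
        params = DenoiseParams()
        f, _, state = _fresh((5, 4, 3), params, rng)
        wrong = build_spectrum((4, 4, 4), params.sigma, params.resolved_weights())
        with pytest.raises(ShapeMismatchError):
            iterate_once(f.copy(), f, state, wrong, params)


class TestReferenceRun:
    def test_printed_call_totals_at_100_iterations(self, rng):
        stack = ImageStack(rng.normal(size=(8, 8, 4)))
        result = denoise_reference(stack, DenoiseParams(iterations=100))
        c = result.counters
        assert c.forward_calls + c.backward_calls == 2400
        assert c.shrink_executions == 600
        assert c.iterations_completed == 100

    def test_constant_stack_is_fixed_point(self):
        stack = ImageStack(np.full((6, 6, 4), 1.5))
        result = denoise_reference(stack, DenoiseParams(iterations=10))
        np.testing.assert_allclose(result.stack.data, stack.data, rtol=0, atol=1e-12)

    def test_mean_preserved(self, small_phantom):
        _, noisy = small_phantom
        result = denoise_reference(noisy, DenoiseParams(iterations=20))
        mean_in = float(noisy.data.astype(np.float64).mean())
        mean_out = float(result.stack.data.mean())
        assert mean_out == pytest.approx(mean_in, abs=1e-10)

    def test_denoises_noisy_phantom(self, small_phantom):
        clean, noisy = small_phantom
        result = denoise_reference(noisy, DenoiseParams(mu=10.0, iterations=30))
        c64 = clean.data.astype(np.float64)
        rmse_in = np.sqrt(np.mean((noisy.data.astype(np.float64) - c64) ** 2))
        rmse_out = np.sqrt(np.mean((result.stack.data - c64) ** 2))
        assert rmse_out < rmse_in


class TestEquivalence:
    def test_binary64_optimized_bit_identical_to_reference(self, fast_params, rng):
        for seed in (1, 2):
            _, noisy = make_phantom(PhantomSpec(shape=(12, 12, 6), seed=seed))
            params = dataclasses.replace(fast_params, precision="binary64")
            ref = denoise_reference(noisy, params)
            opt = denoise_optimized(noisy, params)
            assert opt.stack.data.tobytes() == ref.stack.data.tobytes()

    def test_binary32_differs_bytewise_but_within_tolerance(self, fast_params):
        _, noisy = make_phantom(PhantomSpec(shape=(12, 12, 6), seed=3))
        params64 = dataclasses.replace(fast_params, precision="binary64",
                                       iterations=100)
        params32 = dataclasses.replace(fast_params, precision="binary32",
                                       iterations=100)
        ref = denoise_reference(noisy, params64)
        opt = denoise_optimized(noisy, params32)
        assert opt.stack.data.astype(np.float64).tobytes() != ref.stack.data.tobytes()
        scale = float(np.max(np.abs(ref.stack.data)))
        max_rel = float(np.max(np.abs(
            ref.stack.data - opt.stack.data.astype(np.float64)))) / scale
        assert 0 < max_rel <= 1e-4

    def test_parallel_bit_identical_to_serial(self, fast_params):
        _, noisy = make_phantom(PhantomSpec(shape=(12, 12, 6), seed=4))
        for precision in ("binary32", "binary64"):
            params_s = dataclasses.replace(
                fast_params, precision=precision, backend="cpu_serial")
            params_p = dataclasses.replace(
                fast_params, precision=precision, backend="cpu_parallel")
            serial = denoise_optimized(noisy, params_s)
            parallel = denoise_optimized(noisy, params_p)
            assert parallel.stack.data.tobytes() == serial.stack.data.tobytes()

    def test_repeated_runs_deterministic(self, fast_params):
        _, noisy = make_phantom(PhantomSpec(shape=(10, 10, 5), seed=5))
        outputs = {
            denoise_optimized(noisy, fast_params).stack.data.tobytes()
            for _ in range(3)
        }
        assert len(outputs) == 1


class TestParameterBehavior:
    def test_large_mu_pins_output_to_input(self, small_phantom, cache_dir):
        _, noisy = small_phantom
        rmses = []
        for mu in (1.0, 5.0, 25.0, 125.0):
            params = DenoiseParams(mu=mu, iterations=10, cache_dir=str(cache_dir))
            out = denoise_optimized(noisy, params).stack.data.astype(np.float64)
            rmses.append(float(np.sqrt(np.mean(
                (out - noisy.data.astype(np.float64)) ** 2))))
        assert all(a > b for a, b in zip(rmses, rmses[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DenoiseParams(mu=0)
        with pytest.raises(ValueError):
            DenoiseParams(iterations=0)
        with pytest.raises(ValueError):
            DenoiseParams(sigma=-1)
        with pytest.raises(ValueError):
            DenoiseParams(precision="binary128")

    def test_diagnostics_track_convergence(self, small_phantom, cache_dir):
        _, noisy = small_phantom
        params = DenoiseParams(iterations=5, cache_dir=str(cache_dir),
                               track_diagnostics=True)
        result = denoise_optimized(noisy, params)
        assert len(result.diagnostics) == 5
        assert all("objective" in d and "max_abs_delta" in d
                   for d in result.diagnostics)


class TestDeviceContract:
    def test_device_unavailable_raises_capability_error(self, small_phantom):
        _, noisy = small_phantom
        params = DenoiseParams(iterations=1, backend="device")
        with pytest.raises(DeviceUnavailableError):
            denoise_optimized(noisy, params)

    def test_explicit_fallback_degrades_to_cpu(self, small_phantom, cache_dir):
        _, noisy = small_phantom
        params = DenoiseParams(iterations=2, backend="device", fallback=True,
                               cache_dir=str(cache_dir))
        result = denoise_optimized(noisy, params)
        assert result.backend == "cpu_serial"
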