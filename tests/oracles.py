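"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the package's vectorized code paths: differences
are computed with explicit element loops and the adjoints via explicit
operator matrices, so agreement with the package is meaningful evidence.
"""

import numpy as np


def loop_forward_diff(a: np.ndarray, dim: int) -> np.ndarray:
    """out[i] = a[i+1] - a[i] along dim (1-based), last slice zero."""
    ax = dim - 1
    out = np.zeros_like(a)
    n1, n2, n3 = a.shape
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                idx = [i, j, k]
                if idx[ax] < a.shape[ax] - 1:
                    nxt = list(idx)
                    nxt[ax] += 1
                    out[i, j, k] = a[tuple(nxt)] - a[i, j, k]
    return out


def loop_back_diff(a: np.ndarray, dim: int) -> np.ndarray:
    """out[i] = a[i] - a[i-1] along dim (1-based), first slice zero."""
    ax = dim - 1
    out = np.zeros_like(a)
    n1, n2, n3 = a.shape
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                idx = [i, j, k]
                if idx[ax] > 0:
                    prv = list(idx)
                    prv[ax] -= 1
                    out[i, j, k] = a[i, j, k] - a[tuple(prv)]
    return out


def loop_second_diff(a: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    k, l = dims
    if k == l:
        return loop_back_diff(loop_forward_diff(a, k), k)
    return loop_forward_diff(loop_forward_diff(a, k), l)


def loop_adjoint_forward_diff(a: np.ndarray, dim: int) -> np.ndarray:
    """Elementwise transcription of the forward-difference transpose."""
    ax = dim - 1
    z = a.copy()
    z[tuple(slice(-1, None) if i == ax else slice(None) for i in range(3))] = 0
    out = np.zeros_like(a)
    n1, n2, n3 = a.shape
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                idx = [i, j, k]
                prv = list(idx)
                prv[ax] -= 1
                prev = z[tuple(prv)] if idx[ax] > 0 else 0.0
                out[i, j, k] = prev - z[i, j, k]
    return out


def loop_adjoint_back_diff(a: np.ndarray, dim: int) -> np.ndarray:
    """Elementwise transcription of the backward-difference transpose."""
    ax = dim - 1
    z = a.copy()
    z[tuple(slice(None, 1) if i == ax else slice(None) for i in range(3))] = 0
    out = np.zeros_like(a)
    n1, n2, n3 = a.shape
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                idx = [i, j, k]
                nxt = list(idx)
                nxt[ax] += 1
                nxt_v = z[tuple(nxt)] if idx[ax] < a.shape[ax] - 1 else 0.0
                out[i, j, k] = z[i, j, k] - nxt_v
    return out


def loop_adjoint_second_diff(a: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    k, l = dims
    if k == l:
        return loop_adjoint_forward_diff(loop_adjoint_back_diff(a, k), k)
    return loop_adjoint_forward_diff(loop_adjoint_forward_diff(a, l), k)


def loop_shrink(v: np.ndarray, t: float) -> np.ndarray:
    out = np.zeros_like(v)
    for pos, s in np.ndenumerate(v):
        mag = abs(s) - t
        mag = mag if mag > 0 else 0.0
        sign = 1.0 if s > 0 else (-1.0 if s < 0 else 0.0)
        out[pos] = sign * mag
    return out


def straight_line_iteration(u, f, b, mu, lam, weights, spectrum_values,
                            direction_dims):
    """Transcription of one split-Bregman iteration: loop-based differences
    and shrinkage, the same FFT solve, contributions summed in the given
    direction order.  Returns (u_next, d_arrays, b_arrays)."""
    import scipy.fft

    d_out, b_out, c_sum = {}, {}, None
    for label, dims in direction_dims:
        Du = loop_second_diff(u, dims)
        s = Du + b[label]
        d_new = loop_shrink(s, weights[label] / lam)
        b_new = s - d_new
        c = weights[label] * loop_adjoint_second_diff(d_new - b_new, dims)
        d_out[label] = d_new
        b_out[label] = b_new
        c_sum = c if c_sum is None else c_sum + c
    denom = mu + lam * spectrum_values
    rhs = mu * f + lam * c_sum
    u_next = scipy.fft.ifftn(scipy.fft.fftn(rhs) / denom).real
    return u_next, d_out, b_out


def operator_matrix(op, shape: tuple[int, int, int]) -> np.ndarray:
    """Materialize a linear grid operator as its explicit matrix by applying
    it to every basis vector."""
    n = int(np.prod(shape))
    mat = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        mat[:, j] = op(e.reshape(shape)).ravel()
    return mat
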