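"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: plain
loops and textbook formulas only.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate


def otsu_brute_force(values: np.ndarray) -> int:
    """Exhaustive search of all 256 cut points for max between-class variance.

    Ties broken toward the smallest maximizing threshold.
    """
    v = np.clip(np.rint(np.asarray(values, dtype=np.float64)), 0, 255).astype(int).ravel()
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / v.size
        w1 = hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = t
    return best_t


def dense_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Direct cross-correlation, one output channel at a time."""
    n, c_in, _, _ = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh, kw = w.shape[2], w.shape[3]
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    out = np.zeros((n, c_out, ho, wo))
    for b in range(n):
        for o in range(c_out):
            acc = np.zeros((xp.shape[2] - kh + 1, xp.shape[3] - kw + 1))
            for i in range(c_in):
                acc += correlate(xp[b, i], w[o, i], mode="valid")
            out[b, o] = acc[::stride, ::stride]
    return out


def odconv_oracle(
    x: np.ndarray,
    bank: np.ndarray,
    alpha_s: np.ndarray,
    alpha_c: np.ndarray,
    alpha_f: np.ndarray,
    alpha_w: np.ndarray,
    padding: int,
) -> np.ndarray:
    """Materialize the attention-weighted kernel per sample, then convolve.

    ``bank``: (n, C_out, C_in, k, k); attentions are per-sample arrays of
    shapes (N, k, k), (N, C_in), (N, C_out), (N, n).
    """
    n_kernels = bank.shape[0]
    outs = []
    for b in range(x.shape[0]):
        agg = np.zeros_like(bank[0], dtype=np.float64)
        for i in range(n_kernels):
            mod = bank[i].astype(np.float64).copy()
            for o in range(mod.shape[0]):
                mod[o] *= alpha_f[b, o]
                for c in range(mod.shape[1]):
                    mod[o, c] *= alpha_c[b, c]
                    mod[o, c] *= alpha_s[b]
            agg += alpha_w[b, i] * mod
        outs.append(dense_conv2d(x[b : b + 1].astype(np.float64), agg, padding=padding))
    return np.concatenate(outs, axis=0)


def ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
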