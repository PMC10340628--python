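"""Independent brute-force oracles used by the tests.

These deliberately use naive nested loops / scalar arithmetic so they share
no code path with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def conv1d_bruteforce(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation via explicit loops. x: (C_in, L), W: (C_out, C_in, K)."""
    c_out, c_in, K = W.shape
    L = x.shape[1]
    out = np.zeros((c_out, L - K + 1))
    for j in range(c_out):
        for pos in range(L - K + 1):
            acc = b[j]
            for c in range(c_in):
                for k in range(K):
                    acc += W[j, c, k] * x[c, pos + k]
            out[j, pos] = acc
    return out


def conv2d_bruteforce(I: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Literal flipped-kernel convolution G[m,n] = sum_jk H[j,k] I[m-j,n-k],
    restricted to the valid region."""
    hi, wi = I.shape
    hk, wk = H.shape
    out = np.zeros((hi - hk + 1, wi - wk + 1))
    for m in range(out.shape[0]):
        for n in range(out.shape[1]):
            acc = 0.0
            for j in range(hk):
                for k in range(wk):
                    acc += H[j, k] * I[m + hk - 1 - j, n + wk - 1 - k]
            out[m, n] = acc
    return out


def lstm_step_scalar(x, h_prev, c_prev, wf, wi_, wc, wo, uf, ui, uc, uo,
                     bf, bi, bc, bo):
    """Scalar LSTM cell update with pure-python math.

    Gate weight w* acts on h_prev, u* on x (the concatenation [h, x] split
    into its two coefficients).
    """
    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    f = sig(wf * h_prev + uf * x + bf)
    i = sig(wi_ * h_prev + ui * x + bi)
    ctil = math.tanh(wc * h_prev + uc * x + bc)
    o = sig(wo * h_prev + uo * x + bo)
    c = f * c_prev + i * ctil
    h = o * math.tanh(c)
    return h, c


def moments_bruteforce(X: np.ndarray):
    """Per-column mean, population std, skewness, raw kurtosis via loops."""
    n, d = X.shape
    mean = np.zeros(d)
    std = np.zeros(d)
    skew = np.zeros(d)
    kurt = np.zeros(d)
    for j in range(d):
        m = sum(X[i, j] for i in range(n)) / n
        var = sum((X[i, j] - m) ** 2 for i in range(n)) / n
        mean[j] = m
        std[j] = math.sqrt(var)
        if var > 1e-24:
            m3 = sum((X[i, j] - m) ** 3 for i in range(n)) / n
            m4 = sum((X[i, j] - m) ** 4 for i in range(n)) / n
            skew[j] = m3 / var ** 1.5
            kurt[j] = m4 / var ** 2
    return mean, std, skew, kurt


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f w.r.t. array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def estimate_jitter(samples: np.ndarray, rate: int) -> float:
    """Cycle-length coefficient of variation from zero crossings of the
    low-passed waveform — an f0-perturbation estimate independent of the
    generator's internals."""
    from scipy.signal import butter, filtfilt

    b, a = butter(4, 250.0 / (rate / 2.0), btype="low")
    y = filtfilt(b, a, samples)
    crossings = np.where((y[:-1] <= 0) & (y[1:] > 0))[0]
    periods = np.diff(crossings)
    periods = periods[(periods > rate / 400) & (periods < rate / 60)]
    return float(periods.std() / periods.mean())
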