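"""Small shared signal-processing primitives.

These helpers are deliberately dependency-light: framing, the Teager-Kaiser
energy operator, linear-prediction residuals and band filtering are used by
several dysphonia feature families.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Return a (n_frames, frame_len) view-copy of ``x`` (no padding)."""
    x = np.asarray(x, dtype=float)
    n = 1 + (len(x) - frame_len) // hop if len(x) >= frame_len else 0
    if n <= 0:
        return np.empty((0, frame_len))
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator psi[i] = x[i]^2 - x[i-1]*x[i+1].

    Returns an array of length ``len(x) - 2`` (empty for len < 3).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.empty(0)
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def shannon_entropy(x: np.ndarray, eps: float = 1e-30) -> float:
    """Shannon entropy (nats) of the normalised squared-sample distribution."""
    e = np.asarray(x, dtype=float) ** 2
    tot = e.sum()
    if tot <= eps:
        return 0.0
    p = e / tot
    p = p[p > eps]
    return float(-(p * np.log(p)).sum())


def lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear prediction coefficients [1, -a1, ...].

    The returned vector can be used directly as an FIR whitening filter.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= order:
        raise ValueError("signal shorter than LPC order")
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    if r[0] <= 0:
        raise ValueError("degenerate (zero-energy) signal")
    # tiny diagonal loading keeps the Toeplitz solve well-posed
    r = r.copy()
    r[0] *= 1.0 + 1e-9
    a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    return np.concatenate(([1.0], -a))


def lpc_residual(x: np.ndarray, order: int = 13) -> np.ndarray:
    """Inverse-filter ``x`` with its own LPC model (whitened residual)."""
    a = lpc(x, order)
    return sps.lfilter(a, [1.0], x)


def fft_bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase brick-wall band filter via FFT masking (lo <= f < hi)."""
    n = len(x)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (f >= lo) & (f < hi)
    return np.fft.irfft(X * mask, n)


def parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic interpolation of a peak of ``y`` around index ``i``.

    Returns (fractional index, interpolated value); falls back to the raw
    sample when ``i`` is on the boundary or curvature vanishes.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return i + d, float(b - 0.25 * (a - c) * d)
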