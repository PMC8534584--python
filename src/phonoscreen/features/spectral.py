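"""Mel-frequency cepstral coefficients with delta and delta-delta means."""

from __future__ import annotations

import numpy as np
from scipy.fft import dct

from .._dsp import frame_signal
from ..core import FeatureFlagged, Phonation

_EPS = 1e-30


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, fs: float,
                    f_lo: float = 0.0, f_hi: float = 4000.0) -> np.ndarray:
    f_hi = min(f_hi, fs / 2.0)
    pts = _mel_inv(np.linspace(_mel(f_lo), _mel(f_hi), n_filters + 2))
    bins = np.floor((nfft + 1) * pts / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        b = max(b, a + 1)
        c = max(c, b + 1)
        fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def _delta(c: np.ndarray, width: int = 2) -> np.ndarray:
    """Standard regression delta over +-width frames (edge-padded)."""
    pad = np.pad(c, ((width, width), (0, 0)), mode="edge")
    num = sum(k * (pad[width + k:len(c) + width + k] -
                   pad[width - k:len(c) + width - k]) for k in range(1, width + 1))
    den = 2.0 * sum(k * k for k in range(1, width + 1))
    return num / den


def mfcc_names() -> list[str]:
    return ([f"mfcc.c{i}" for i in range(13)]
            + [f"mfcc.d{i}" for i in range(13)]
            + [f"mfcc.dd{i}" for i in range(13)])


def mfcc_family(segment: Phonation, n_coeffs: int = 13,
                n_filters: int = 26) -> np.ndarray:
    """39 measures: frame-averaged c0..c12 and their delta / delta-delta.

    25 ms Hamming frames with 10 ms hop; 26 triangular mel filters over
    0-4 kHz; log filterbank energies followed by an orthonormal DCT-II.
    """
    fs = segment.fs
    frame_len = int(0.025 * fs)
    hop = int(0.010 * fs)
    frames = frame_signal(segment.samples, frame_len, hop)
    if len(frames) < 10:
        raise FeatureFlagged("mfcc", f"only {len(frames)} frames")
    frames = frames * np.hamming(frame_len)
    nfft = int(2 ** np.ceil(np.log2(frame_len)))
    spec = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2
    fb = _mel_filterbank(n_filters, nfft, fs)
    mel_e = spec @ fb.T
    # floor at -60 dB of the frame total: windowing leakage into empty
    # bands is phase-dependent and would otherwise dominate the log scale.
    # The floor scales with signal energy, preserving gain invariance.
    floor = 1e-6 * spec.sum(axis=1, keepdims=True) + _EPS
    logmel = np.log(np.maximum(mel_e, floor))
    ceps = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    d1 = _delta(ceps)
    d2 = _delta(d1)
    return np.concatenate([ceps.mean(axis=0), d1.mean(axis=0), d2.mean(axis=0)])
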