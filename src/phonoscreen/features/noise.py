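"""Noise-related families: HNR/NHR, glottal-to-noise excitation, VFER.

All three families quantify the aspiration/turbulent-noise content of the
phonation: HNR/NHR from the normalised autocorrelation peak, GNE from the
cross-band correlation of Hilbert envelopes of the inverse-filtered
residual, and VFER from energy/nonlinear-energy/entropy ratios between the
band below 2.5 kHz (vocal-fold excitation) and the band above it.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .._dsp import (fft_bandpass, frame_signal, lpc_residual,
                    parabolic_refine, shannon_entropy, tkeo)
from ..core import FeatureFlagged, Phonation
from ..pitch import F0Contour

_EPS = 1e-12


# ---------------------------------------------------------------------------
# HNR / NHR


def hnr_names() -> list[str]:
    return ["hnr.hnr_mean", "hnr.hnr_sd", "hnr.nhr_mean", "hnr.nhr_sd"]


def hnr_nhr(segment: Phonation, f0: F0Contour) -> np.ndarray:
    """Mean/SD over frames of autocorrelation HNR (dB) and NHR."""
    fs = segment.fs
    frame_len = int(0.040 * fs)
    hop = int(0.010 * fs)
    frames = frame_signal(segment.samples, frame_len, hop)
    vt, vf = f0.voiced_times(), f0.voiced_f0()
    if len(vf) == 0:
        raise FeatureFlagged("hnr", "no voiced frames")
    hnrs, nhrs = [], []
    for i, fr in enumerate(frames):
        t = i * 0.010 + frame_len / fs / 2.0
        cand = vf[np.argmin(np.abs(vt - t))]
        lag0 = fs / cand
        lags = np.arange(max(int(0.7 * lag0), 2), int(1.3 * lag0) + 2)
        if lags[-1] >= frame_len - 2:
            continue
        fr = fr - fr.mean()
        e0 = np.dot(fr, fr)
        if e0 <= 0:
            continue
        rs = np.full(len(lags), -1.0)
        for k, lag in enumerate(lags):
            a, b = fr[:-lag], fr[lag:]
            denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
            if denom > 0:
                rs[k] = float(np.dot(a, b) / denom)
        # refine the peak between integer lags: the quantisation otherwise
        # caps HNR at ~15 dB for perfectly periodic input
        _, best = parabolic_refine(rs, int(np.argmax(rs)))
        r = min(max(best, _EPS), 1.0 - 1e-12)
        hnrs.append(10.0 * np.log10(r / (1.0 - r)))
        nhrs.append((1.0 - r) / r)
    if not hnrs:
        raise FeatureFlagged("hnr", "no usable frames")
    return np.asarray([np.mean(hnrs), np.std(hnrs), np.mean(nhrs), np.std(nhrs)])


# ---------------------------------------------------------------------------
# GNE


def gne_names() -> list[str]:
    return ["gne.gne_mean", "gne.gne_sd", "gne.snr_seo_mean",
            "gne.snr_seo_sd", "gne.snr_tkeo_mean", "gne.snr_tkeo_sd"]


def _band_envelopes(residual: np.ndarray, fs: float,
                    centers: np.ndarray, width: float) -> np.ndarray:
    envs = []
    for c in centers:
        lo = max(c - width / 2.0, 0.0)
        hi = min(c + width / 2.0, fs / 2.0)
        band = fft_bandpass(residual, fs, lo, hi)
        envs.append(np.abs(hilbert(band)))
    return np.asarray(envs)


def _max_crosscorr(e1: np.ndarray, e2: np.ndarray, max_lag: int = 3) -> float:
    a = e1 - e1.mean()
    b = e2 - e2.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            u, v = a[lag:], b[: len(b) - lag]
        else:
            u, v = a[: len(a) + lag], b[-lag:]
        best = max(best, float(np.dot(u, v)))
    return best / (na * nb)


def gne_family(segment: Phonation, lpc_order: int = 13) -> np.ndarray:
    """6 glottal-to-noise excitation measures on the LPC residual.

    Band centres run every 500 Hz up to 3.5 kHz (adapted to 8 kHz material)
    with 1 kHz-wide bands; GNE per frame is the maximum envelope
    cross-correlation between bands at least 1500 Hz apart.
    """
    fs = segment.fs
    try:
        residual = lpc_residual(segment.samples, lpc_order)
    except ValueError as exc:
        raise FeatureFlagged("gne", f"LPC failure: {exc}") from exc
    centers = np.arange(500.0, min(3500.0, fs / 2.0 - 400.0) + 1, 500.0)
    frame_len = int(0.100 * fs)
    hop = int(0.050 * fs)
    frames = frame_signal(residual, frame_len, hop)
    if len(frames) < 2:
        raise FeatureFlagged("gne", "segment too short")
    pairs = [(i, j) for i in range(len(centers)) for j in range(len(centers))
             if centers[j] - centers[i] >= 1500.0]
    gnes, snr_seo, snr_tkeo = [], [], []
    for fr in frames:
        envs = _band_envelopes(fr, fs, centers, 1000.0)
        rho = max(_max_crosscorr(envs[i], envs[j]) for i, j in pairs)
        rho = min(max(rho, 0.0), 1.0 - 1e-9)
        gnes.append(rho)
        # correlated (excitation-driven) vs uncorrelated envelope energy
        snr_seo.append(10.0 * np.log10(rho**2 / (1.0 - rho**2) + _EPS))
        psi = np.asarray([np.mean(np.abs(tkeo(e))) for e in envs])
        lo_e = psi[: len(psi) // 2].mean()
        hi_e = psi[len(psi) // 2:].mean()
        snr_tkeo.append(10.0 * np.log10(lo_e / (hi_e + _EPS) + _EPS))
    return np.asarray([np.mean(gnes), np.std(gnes),
                       np.mean(snr_seo), np.std(snr_seo),
                       np.mean(snr_tkeo), np.std(snr_tkeo)])


# ---------------------------------------------------------------------------
# VFER


def vfer_names() -> list[str]:
    return ["vfer.energy_mean", "vfer.energy_sd", "vfer.tkeo_mean",
            "vfer.tkeo_sd", "vfer.entropy_mean", "vfer.entropy_sd",
            "vfer.energy_global", "vfer.tkeo_global", "vfer.entropy_global"]


def vfer_family(segment: Phonation, split_hz: float = 2500.0) -> np.ndarray:
    """9 vocal-fold excitation ratio measures around the 2.5 kHz split."""
    fs = segment.fs
    x = segment.samples
    low = fft_bandpass(x, fs, 0.0, split_hz)
    high = fft_bandpass(x, fs, split_hz, fs / 2.0)
    frame_len = int(0.025 * fs)
    hop = int(0.010 * fs)
    fl = frame_signal(low, frame_len, hop)
    fh = frame_signal(high, frame_len, hop)
    e_ratio, t_ratio, h_ratio = [], [], []
    for a, b in zip(fl, fh):
        ea, eb = float(np.mean(a**2)), float(np.mean(b**2))
        if ea <= _EPS and eb <= _EPS:
            continue  # silent frame
        e_ratio.append(ea / max(eb, _EPS))
        ta = float(np.mean(np.abs(tkeo(a))))
        tb = float(np.mean(np.abs(tkeo(b))))
        if ta > _EPS or tb > _EPS:
            t_ratio.append(ta / max(tb, _EPS))
        ha, hb = shannon_entropy(a), shannon_entropy(b)
        if ha > _EPS or hb > _EPS:
            h_ratio.append(ha / max(hb, _EPS))
    if not e_ratio:
        raise FeatureFlagged("vfer", "no energetic frames")
    e_glob = float(np.mean(low**2) / max(np.mean(high**2), _EPS))
    t_glob = float(np.mean(np.abs(tkeo(low))) / max(np.mean(np.abs(tkeo(high))), _EPS))
    h_glob = float(shannon_entropy(low) / max(shannon_entropy(high), _EPS))
    return np.asarray([np.mean(e_ratio), np.std(e_ratio),
                       np.mean(t_ratio), np.std(t_ratio),
                       np.mean(h_ratio), np.std(h_ratio),
                       e_glob, t_glob, h_glob])
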