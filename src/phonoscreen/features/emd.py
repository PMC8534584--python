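"""Empirical mode decomposition and EMD-based excitation ratios.

A standard sifting implementation (cubic-spline envelopes, Cauchy-like SD
stopping criterion of 0.2) splits the phonation into intrinsic mode
functions; the first two IMFs carry the highest-frequency content and are
treated as the noise part, the remainder as the signal part.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .._dsp import shannon_entropy, tkeo
from ..core import FeatureFlagged, Phonation

_EPS = 1e-12


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    up = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    down = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    return up, down


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = _extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(x)
    # mirror the end extrema so the splines cover the full support
    mx = np.concatenate(([0], maxima, [n - 1]))
    my = np.concatenate(([x[maxima[0]]], x[maxima], [x[maxima[-1]]]))
    mnx = np.concatenate(([0], minima, [n - 1]))
    mny = np.concatenate(([x[minima[0]]], x[minima], [x[minima[-1]]]))
    upper = CubicSpline(mx, my)(np.arange(n))
    lower = CubicSpline(mnx, mny)(np.arange(n))
    return 0.5 * (upper + lower)


def emd(x: np.ndarray, max_imfs: int = 8, sd_stop: float = 0.2,
        max_sift: int = 30) -> list[np.ndarray]:
    """Decompose ``x`` into IMFs by sifting; the residual is appended last."""
    x = np.asarray(x, dtype=float)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual.copy()
        for _ in range(max_sift):
            m = _mean_envelope(h)
            if m is None:
                break
            h_new = h - m
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2) / (denom + _EPS))
            h = h_new
            if sd < sd_stop:
                break
        if _mean_envelope(h) is None and not imfs:
            break
        imfs.append(h)
        residual = residual - h
        up, down = _extrema(residual)
        if len(up) + len(down) < 4:
            break
    imfs.append(residual)
    return imfs


def emd_er_names() -> list[str]:
    return ["emd_er.energy_db", "emd_er.energy_raw", "emd_er.tkeo_db",
            "emd_er.tkeo_raw", "emd_er.entropy_db", "emd_er.entropy_raw"]


def emd_er_family(segment: Phonation) -> np.ndarray:
    """6 EMD excitation-ratio measures (energy, TKEO, entropy; raw and dB).

    The signal part is the single dominant-energy IMF (the vocal-fold
    excitation mode); all other modes form the noise part.  A clean
    sustained vowel concentrates its energy in one mode whereas broadband
    noise spreads energy across scales.  Leading-IMF-count noise
    definitions are unusable on telephone-band material, where EMD places
    the first-formant oscillation itself in the first IMF.
    """
    if segment.duration < 1.0:
        raise FeatureFlagged("emd_er", "segment shorter than 1 s")
    imfs = emd(segment.samples)
    if len(imfs) < 3:
        raise FeatureFlagged("emd_er", f"only {len(imfs)} IMFs")
    energies = [float(np.sum(im**2)) for im in imfs]
    k = int(np.argmax(energies))
    sig = imfs[k]
    noise = np.sum([im for i, im in enumerate(imfs) if i != k], axis=0)

    e_ratio = float(np.sum(sig**2) / max(np.sum(noise**2), _EPS))
    t_sig = float(np.mean(np.abs(tkeo(sig))))
    t_noise = float(np.mean(np.abs(tkeo(noise))))
    t_ratio = t_sig / max(t_noise, _EPS)
    h_ratio = shannon_entropy(sig) / max(shannon_entropy(noise), _EPS)
    return np.asarray([
        10.0 * np.log10(e_ratio + _EPS), e_ratio,
        10.0 * np.log10(t_ratio + _EPS), t_ratio,
        10.0 * np.log10(h_ratio + _EPS), h_ratio,
    ])
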