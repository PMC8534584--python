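"""F0-contour-based families: normative F0 comparison, wavelet battery, PPE.

These measures act on the 10 ms pitch track rather than the waveform: slow
F0 instabilities (tremor, drift, pathological variability) live at contour
time scales that waveform measures cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import detrend
from scipy.stats import norm

from .._dsp import tkeo
from ..core import FeatureFlagged
from ..pitch import F0Contour

_EPS = 1e-12


# ---------------------------------------------------------------------------
# F0 vs normative table


@dataclass(frozen=True)
class NormativeF0Table:
    """Healthy-control log-F0 statistics per gender (natural-log Hz).

    The defaults (120 Hz male / 200 Hz female, 0.15 log-Hz SD) are
    conventional adult values and are configuration, not claims.
    """

    mean_log_f0: dict = field(default_factory=lambda: {
        "M": float(np.log(120.0)), "F": float(np.log(200.0))})
    sd_log_f0: dict = field(default_factory=lambda: {"M": 0.15, "F": 0.15})


def f0_related_names() -> list[str]:
    return ["f0_related.z_score", "f0_related.tail_prob", "f0_related.sd_ratio"]


def f0_related_family(f0: F0Contour, age: float, gender: str,
                      norms: NormativeF0Table = NormativeF0Table()) -> np.ndarray:
    """3 comparisons of the observed F0 against matched-control norms."""
    if gender not in norms.mean_log_f0:
        raise FeatureFlagged("f0_related", f"no norms for gender {gender!r}")
    vf = f0.voiced_f0()
    if len(vf) < 10:
        raise FeatureFlagged("f0_related", "too few voiced frames")
    log_f0 = np.log(vf)
    mu, sd = norms.mean_log_f0[gender], norms.sd_log_f0[gender]
    z = float((log_f0.mean() - mu) / sd)
    tail = float(2.0 * (1.0 - norm.cdf(abs(z))))
    sd_ratio = float(np.std(log_f0) / sd)
    return np.asarray([z, tail, sd_ratio])


# ---------------------------------------------------------------------------
# wavelet battery


_WT_BAND_STATS = ["log_energy", "entropy", "log_energy_entropy",
                  "tkeo_mean", "tkeo_sd", "max_abs", "iqr"]
_WT_LEVELS = 10
_WAVELET = "db8"


def _band_names(prefix: str) -> list[str]:
    bands = [f"d{k}" for k in range(1, _WT_LEVELS + 1)] + [f"a{_WT_LEVELS}"]
    names = [f"wavelet.{prefix}.{b}.{s}" for b in bands for s in _WT_BAND_STATS]
    names += [f"wavelet.{prefix}.{b}.energy_fraction" for b in bands]
    names += [f"wavelet.{prefix}.detail_fraction",
              f"wavelet.{prefix}.band_entropy",
              f"wavelet.{prefix}.energy_slope"]
    return names


def wavelet_names() -> list[str]:
    return _band_names("f0") + _band_names("logf0")


def _band_stats(c: np.ndarray) -> list[float]:
    e = float(np.sum(c**2))
    p = c**2 / (e + _EPS)
    p = p[p > _EPS]
    entropy = float(-(p * np.log(p)).sum()) if p.size else 0.0
    log_energy_entropy = float(np.sum(np.log(c**2 + _EPS)))
    psi = tkeo(c)
    t_mean = float(np.mean(psi)) if psi.size else 0.0
    t_sd = float(np.std(psi)) if psi.size else 0.0
    return [float(np.log10(e + _EPS)), entropy, log_energy_entropy,
            t_mean, t_sd, float(np.max(np.abs(c))) if c.size else 0.0,
            float(np.subtract(*np.percentile(c, [75, 25]))) if c.size else 0.0]


def _wavelet_block(x: np.ndarray) -> list[float]:
    x = detrend(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, _WAVELET, level=_WT_LEVELS,
                              mode="periodization")
    # wavedec returns [a_L, d_L, ..., d_1]; reorder to d1..dL, aL
    approx, details = coeffs[0], coeffs[1:]
    bands = details[::-1] + [approx]
    vals: list[float] = []
    for c in bands:
        vals += _band_stats(c)
    energies = np.array([np.sum(c**2) for c in bands])
    total = energies.sum() + _EPS
    vals += list(energies / total)
    detail_fraction = float(energies[:-1].sum() / total)
    pe = energies / total
    pe = pe[pe > _EPS]
    band_entropy = float(-(pe * np.log(pe)).sum())
    # slope of log detail energy vs level: spectral tilt of the contour
    lev = np.arange(1, _WT_LEVELS + 1)
    slope = float(np.polyfit(lev, np.log10(energies[:-1] + _EPS), 1)[0])
    vals += [detail_fraction, band_entropy, slope]
    return vals


def wavelet_family(f0: F0Contour, min_frames: int = 128) -> np.ndarray:
    """182 wavelet measures of the F0 contour and its logarithm.

    Ten-level Daubechies-8 decomposition (periodised) of the detrended
    voiced contour; per band: log energy, Shannon entropy of normalised
    squared coefficients, log-energy entropy, TKEO mean/SD, max |c|, IQR,
    and the band's energy fraction; plus detail-energy fraction, cross-band
    energy entropy and the log-energy-vs-level slope per input.
    """
    vf = f0.voiced_f0()
    if len(vf) < min_frames:
        raise FeatureFlagged("wavelet", f"only {len(vf)} voiced frames")
    return np.asarray(_wavelet_block(vf) + _wavelet_block(np.log(vf)))


# ---------------------------------------------------------------------------
# pitch period entropy


def ppe_names() -> list[str]:
    return ["ppe.ppe"]


def ppe(f0: F0Contour, n_bins: int = 60, semitone_range: float = 12.0,
        min_frames: int = 50) -> np.ndarray:
    """Pitch period entropy of the whitened semitone-scale pitch sequence.

    The contour is expressed in semitones around its median, whitened with
    an order-2 linear predictor (which removes healthy slow drift), and the
    residual distribution's normalised entropy is returned in [0, 1].
    """
    vf = f0.voiced_f0()
    if len(vf) < min_frames:
        raise FeatureFlagged("ppe", "too few voiced frames")
    s = 12.0 * np.log2(vf / np.median(vf))
    if np.allclose(s, s[0]):
        return np.asarray([0.0])
    # order-2 least-squares predictor with intercept
    X = np.column_stack([s[1:-1], s[:-2], np.ones(len(s) - 2)])
    coef, *_ = np.linalg.lstsq(X, s[2:], rcond=None)
    resid = s[2:] - X @ coef
    if np.ptp(resid) < 1e-9:  # perfectly predictable contour
        return np.asarray([0.0])
    hist, _ = np.histogram(resid, bins=n_bins,
                           range=(-semitone_range, semitone_range))
    total = hist.sum()
    if total == 0:
        return np.asarray([0.0])
    q = hist / total
    q = q[q > 0]
    return np.asarray([float(-(q * np.log(q)).sum() / np.log(n_bins))])
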