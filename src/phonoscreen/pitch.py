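"""F0 contour estimation and glottal-cycle extraction.

The contour estimator follows the sawtooth-waveform-inspired (SWIPE-family)
spectral-matching idea: for every 10 ms frame the square-root magnitude
spectrum, interpolated onto an ERB-spaced grid, is correlated against a
pitch-candidate kernel whose positive cosine lobes sit at the candidate's
harmonics, with only the first and the prime-numbered harmonics contributing
(the SWIPE' refinement that suppresses sub-harmonic confusion).  Candidates
live on a 1/96-octave log grid; the winning candidate is refined by parabolic
interpolation of the strength curve and frames whose pitch strength falls
below a voicing threshold are marked unvoiced.

A single analysis window sized for four periods of ``f_min`` is used for all
candidates; the ERB-grid interpolation of the spectrum is retained.  Accuracy
on clean sustained vowels is bounded in the test-suite against an independent
autocorrelation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._dsp import parabolic_refine
from .core import Phonation, PhonoscreenError

#: default voicing decision threshold on pitch strength
VOICING_THRESHOLD = 0.3

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)


@dataclass
class F0Contour:
    """Pitch track on a fixed 10 ms grid.

    Unvoiced frames carry ``f0 = nan``; ``strength`` is in [0, 1].
    """

    times: np.ndarray
    f0: np.ndarray
    strength: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    def voiced_times(self) -> np.ndarray:
        return self.times[self.voiced]

    def f0_at(self, t: float) -> float:
        """Nearest-voiced-frame F0 lookup (nan when no voiced frame exists)."""
        vt, vf = self.voiced_times(), self.voiced_f0()
        if len(vt) == 0:
            return float("nan")
        return float(vf[np.argmin(np.abs(vt - t))])


@dataclass
class CycleSequence:
    """Glottal cycle marks with per-cycle period and peak amplitude."""

    cycle_marks: np.ndarray   # seconds
    periods: np.ndarray       # T_i = mark_{i+1} - mark_i
    amplitudes: np.ndarray    # per-cycle absolute waveform extremum

    def __post_init__(self) -> None:
        assert len(self.periods) == len(self.cycle_marks) - 1
        assert len(self.amplitudes) == len(self.periods)
        if np.any(self.periods <= 0):
            raise ValueError("cycle periods must be positive")


def _erb(f: np.ndarray) -> np.ndarray:
    return 21.4 * np.log10(1.0 + 0.00437 * f)


def _erb_inv(e: np.ndarray) -> np.ndarray:
    return (10.0 ** (e / 21.4) - 1.0) / 0.00437


@lru_cache(maxsize=8)
def _kernel_bank(fs: float, nfft: int, f_min: float, f_max: float):
    """Candidate kernels sampled on an ERB grid; cached per configuration."""
    n_cand = int(np.ceil(96.0 * np.log2(f_max / f_min))) + 1
    candidates = f_min * 2.0 ** (np.arange(n_cand) / 96.0)
    # ERB-spaced frequency grid covering the usable band
    e_lo, e_hi = _erb(np.array([f_min * 0.8, fs / 2.0]))
    grid = _erb_inv(np.arange(e_lo, e_hi, 0.05))
    K = np.zeros((n_cand, len(grid)))
    for i, p in enumerate(candidates):
        x = grid / p                       # harmonic-number coordinate
        n = np.round(x)
        max_h = int(fs / 2.0 / p)
        valid = (n >= 1) & (n <= max_h) & (
            (n == 1) | np.isin(n, _PRIMES))
        lobe = np.cos(2.0 * np.pi * x)
        d = np.abs(x - n)
        in_band = (x >= 0.75) & (x <= max_h + 0.25)
        # narrow positive lobes at admitted harmonics (half the cosine lobe
        # width, so neighbouring-harmonic energy cannot leak in); half-weight
        # negative lobes between harmonics penalise inter-harmonic energy.
        # The positive and (weighted) negative lobe areas balance, so a flat
        # noise spectrum scores ~0.
        pos = valid & (d < 0.125)
        neg = in_band & (lobe < 0)
        K[i] = np.where(pos, np.cos(4.0 * np.pi * (x - n)), 0.0) \
            + np.where(neg, 0.5 * lobe, 0.0)
        # decay kernel weight as 1/sqrt(f): matches sawtooth spectral envelope
        K[i] *= 1.0 / np.sqrt(np.maximum(grid, 1.0))
        # normalise by the positive-lobe norm: a spectrum matching the
        # harmonic template exactly then scores 1, inter-harmonic energy
        # only subtracts
        norm = np.linalg.norm(np.maximum(K[i], 0.0))
        if norm > 0:
            K[i] /= norm
    support = (K != 0).astype(float)
    fft_freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return candidates, grid, K, support, fft_freqs


def estimate_f0_contour(p: Phonation, f_min: float = 50.0,
                        f_max: float = 500.0,
                        voicing_threshold: float = VOICING_THRESHOLD) -> F0Contour:
    """Estimate the F0 contour every 10 ms with a spectral-matching estimator."""
    if f_min >= f_max:
        raise PhonoscreenError("f_min must be below f_max")
    fs = p.fs
    hop = int(round(0.010 * fs))
    win_len = int(round(4.0 / f_min * fs))
    nfft = int(2 ** np.ceil(np.log2(win_len * 2)))
    candidates, grid, K, support, fft_freqs = _kernel_bank(fs, nfft, f_min, f_max)

    x = p.samples
    half = win_len // 2
    xp = np.pad(x, (half, half))
    n_frames = len(x) // hop
    window = np.hanning(win_len)

    times = np.empty(n_frames)
    f0 = np.full(n_frames, np.nan)
    strength = np.zeros(n_frames)

    # frame the (centred) signal and take sqrt-magnitude spectra in one go
    starts = hop * np.arange(n_frames)
    idx = starts[:, None] + np.arange(win_len)[None, :]
    frames = xp[idx] * window
    spectra = np.sqrt(np.abs(np.fft.rfft(frames, nfft, axis=1)))
    # interpolate each spectrum onto the ERB grid
    S = np.empty((n_frames, len(grid)))
    for j in range(n_frames):
        S[j] = np.interp(grid, fft_freqs, spectra[j])
    # SWIPE-style normalisation: each candidate's strength is the cosine
    # between the kernel and the spectrum restricted to the kernel's support
    norms = np.linalg.norm(S, axis=1)
    ok = norms > 0
    scores = np.zeros((n_frames, len(candidates)))
    raw = S[ok] @ K.T
    local_norm = np.sqrt((S[ok] ** 2) @ support.T)
    scores[ok] = raw / np.maximum(local_norm, 1e-12)

    # sustained-vowel prior: anchor the candidate search around the segment's
    # dominant period (from the whole-signal autocorrelation), which guards
    # against formant-envelope pitch errors when heavy jitter has destroyed
    # the harmonic fine structure
    anchor = _autocorr_anchor(x, fs, f_min, f_max)
    if anchor is not None:
        width = 0.45  # octaves either side of the anchor
        sel = np.abs(np.log2(candidates / anchor)) <= width
        if sel.sum() >= 3:
            scores[:, ~sel] = -np.inf

    # frame-level temporal periodicity: the normalised autocorrelation at the
    # winning period supplements the spectral-match strength, so heavily
    # jittered (but clearly voiced) frames are not discarded
    times[:] = starts / fs
    for j in range(n_frames):
        if not ok[j]:
            continue
        i = int(np.argmax(scores[j]))
        # parabolic refinement on the log-frequency candidate grid
        fi, sv = parabolic_refine(np.nan_to_num(scores[j], neginf=-1.0), i)
        cand_f0 = float(f_min * 2.0 ** (fi / 96.0))
        if sv < voicing_threshold + 0.1:
            sv = max(sv, _frame_periodicity(xp, starts[j], win_len, fs, cand_f0))
        s = min(max(sv, 0.0), 1.0)
        strength[j] = s
        if s >= voicing_threshold:
            f0[j] = cand_f0
    return F0Contour(times=times, f0=f0, strength=strength)


def _autocorr_anchor(x: np.ndarray, fs: float, f_min: float,
                     f_max: float) -> float | None:
    """Dominant F0 of the signal from its amplitude-envelope autocorrelation.

    The Hilbert envelope strips the formant oscillation (which otherwise
    produces spurious ringing lags) while keeping the pulse-rate
    periodicity, and its periodicity survives heavy cycle-timing jitter.
    Returns None for aperiodic input.
    """
    from scipy.signal import hilbert
    env = np.abs(hilbert(np.asarray(x, dtype=float)))
    env = env - env.mean()
    e = float(np.dot(env, env))
    if e <= 0:
        return None
    n = len(env)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(env, nfft)
    ac = np.fft.irfft(X * np.conj(X), nfft)[: n] / e
    lo = int(np.floor(fs / f_max))
    hi = int(np.ceil(fs / f_min))
    if 4 * hi >= n:
        return None
    lags = np.arange(lo, hi + 1)
    if ac[lags].max() < 0.2:
        return None
    # comb evidence: a true period is supported at all its multiples,
    # whereas formant-ringing lags and half-periods are not; the smallest
    # near-maximal lag wins, which rejects period doubling.  A +-2 sample
    # local-max filter lets integer lags see the true (fractional) peaks.
    from scipy.ndimage import maximum_filter1d
    acmax = maximum_filter1d(ac[: 4 * hi + 3], size=5)
    score = np.mean([acmax[k * lags] for k in (1, 2, 3, 4)], axis=0)
    m = float(score.max())
    first = lo + int(np.argmax(score >= 0.9 * m))
    # refine to the local peak around that lag
    j = first
    while j + 1 <= hi and ac[j + 1] > ac[j]:
        j += 1
    while j - 1 >= lo and ac[j - 1] > ac[j]:
        j -= 1
    fj, _ = parabolic_refine(ac, j)
    return float(fs / fj)


def _frame_periodicity(xp: np.ndarray, start: int, win_len: int, fs: float,
                       cand_f0: float) -> float:
    """Normalised autocorrelation of one (padded) frame near lag 1/cand_f0."""
    fr = xp[start: start + win_len]
    fr = fr - fr.mean()
    lag0 = fs / cand_f0
    lags = np.arange(max(int(0.85 * lag0), 2), int(1.15 * lag0) + 2)
    if lags[-1] >= len(fr) - 2:
        return 0.0
    best = 0.0
    for lag in lags:
        a, b = fr[:-lag], fr[lag:]
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        if denom > 0:
            best = max(best, float(np.dot(a, b) / denom))
    return best


def extract_cycles(p: Phonation, f0: F0Contour) -> CycleSequence:
    """Locate one dominant waveform extremum per glottal cycle.

    Marks are seeded from the contour and advanced with a local search window
    of 0.7-1.3 times the current period estimate; peak positions and values
    are refined by parabolic interpolation so the period resolution is finer
    than one sample.
    """
    if int(np.sum(f0.voiced)) < 3:
        raise PhonoscreenError("fewer than 3 voiced frames")
    x = p.samples
    fs = p.fs
    vt = f0.voiced_times()
    t0 = float(vt[0])

    # choose waveform polarity from the first voiced period
    i0 = int(t0 * fs)
    T0 = 1.0 / f0.f0_at(t0)
    seg = x[i0: i0 + int(1.5 * T0 * fs)]
    if len(seg) < 3:
        raise PhonoscreenError("signal too short for cycle extraction")
    sign = 1.0 if abs(seg.max()) >= abs(seg.min()) else -1.0
    y = sign * x

    i_peak = i0 + int(np.argmax(y[i0: i0 + int(1.5 * T0 * fs)]))
    fi, _ = parabolic_refine(y, i_peak)
    marks = [fi / fs]
    t_end = float(vt[-1]) + 0.010
    while True:
        t = marks[-1]
        cur_f0 = f0.f0_at(t)
        if not np.isfinite(cur_f0):
            break
        T = 1.0 / cur_f0
        lo = int(round((t + 0.7 * T) * fs))
        hi = int(round((t + 1.3 * T) * fs))
        # keep most of a period clear of the signal edge: the final cycle's
        # formant response runs into the boundary and its peak is unreliable
        if hi >= len(y) - int(0.7 * T * fs) or t + T > t_end:
            break
        j = lo + int(np.argmax(y[lo:hi]))
        fj, _ = parabolic_refine(y, j)
        marks.append(fj / fs)
    if len(marks) < 4:
        raise PhonoscreenError("fewer than 3 cycles found")

    marks_arr = np.asarray(marks)
    periods = np.diff(marks_arr)
    amps = np.empty(len(periods))
    absx = np.abs(x)
    for i in range(len(periods)):
        a = int(round(marks_arr[i] * fs))
        b = max(int(round(marks_arr[i + 1] * fs)), a + 2)
        b = min(b, len(x))
        j = a + int(np.argmax(absx[a:b]))
        _, v = parabolic_refine(absx, j)
        amps[i] = abs(v)
    return CycleSequence(cycle_marks=marks_arr, periods=periods, amplitudes=amps)
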