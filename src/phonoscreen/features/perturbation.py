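"""Cycle-perturbation families: jitter variants, shimmer variants, GQ.

The classical period/amplitude perturbation quotients (local jitter, RAP,
PPQ5, DDP, local shimmer, shimmer dB, APQ3/5/11, DDA) are mandatory; the
remaining slots of each family are filled by a fixed, systematically
generated grid of variants (mean vs median aggregation, raw vs log
sequences, cycle-level vs 10 ms frame-level source sequences, TKEO-based
statistics).  The enumeration is frozen in the feature manifest.
"""

from __future__ import annotations

import numpy as np

from .._dsp import frame_signal, tkeo
from ..core import FeatureFlagged, Phonation
from ..pitch import CycleSequence, F0Contour

MIN_CYCLES = 12


# ---------------------------------------------------------------------------
# perturbation statistics on a generic positive sequence


def _local(seq: np.ndarray, agg) -> float:
    """agg |x_i - x_{i+1}| / agg x."""
    return float(agg(np.abs(np.diff(seq))) / agg(seq))


def _local_absolute(seq: np.ndarray, agg) -> float:
    return float(agg(np.abs(np.diff(seq))))


def _log_local(seq: np.ndarray, agg) -> float:
    return float(agg(np.abs(np.diff(np.log(seq)))))


def _ppq(seq: np.ndarray, k: int, agg=np.mean) -> float:
    """k-point period perturbation quotient (neighbourhood-mean reference)."""
    half = k // 2
    n = len(seq)
    if n < k:
        return float("nan")
    centers = seq[half: n - half]
    neigh = np.array([seq[i - half: i + half + 1].mean()
                      for i in range(half, n - half)])
    return float(agg(np.abs(centers - neigh)) / np.mean(seq))


def _ddp(seq: np.ndarray) -> float:
    """Mean absolute difference of consecutive first differences / mean."""
    d = np.diff(seq)
    return float(np.mean(np.abs(np.diff(d))) / np.mean(seq))


def _tkeo_stats(seq: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the TKEO of the mean-normalised sequence."""
    psi = tkeo(seq / np.mean(seq))
    if psi.size == 0:
        return 0.0, 0.0
    return float(np.mean(psi)), float(np.std(psi))


def _perturbation_block(seq: np.ndarray) -> list[float]:
    """The 14 jitter-style statistics of one source sequence."""
    out = [
        _local(seq, np.mean),
        _local(seq, np.median),
        _local_absolute(seq, np.mean),
        _local_absolute(seq, np.median),
        _ppq(seq, 3, np.mean),       # RAP
        _ppq(seq, 3, np.median),
        _ppq(seq, 5, np.mean),       # PPQ5
        _ppq(seq, 5, np.median),
        _ddp(seq),
        _log_local(seq, np.mean),
        _log_local(seq, np.median),
    ]
    m, s = _tkeo_stats(seq)
    out += [m, s]
    out.append(float(np.std(seq) / np.mean(seq)))  # coefficient of variation
    return out


_BLOCK_STATS = [
    "local_mean", "local_median", "abs_mean", "abs_median",
    "rap", "rap_median", "ppq5", "ppq5_median", "ddp",
    "log_local_mean", "log_local_median", "tkeo_mean", "tkeo_sd", "cv",
]


def jitter_names() -> list[str]:
    return [f"jitter.{src}.{s}" for src in ("cycle", "frame")
            for s in _BLOCK_STATS]


def jitter_family(c: CycleSequence, f0: F0Contour) -> np.ndarray:
    """28 F0-perturbation measures from cycle periods and frame periods."""
    T = np.asarray(c.periods, dtype=float)
    if len(T) < MIN_CYCLES:
        raise FeatureFlagged("jitter", f"only {len(T)} periods (<{MIN_CYCLES})")
    P = 1.0 / f0.voiced_f0()
    if len(P) < MIN_CYCLES:
        raise FeatureFlagged("jitter", "too few voiced contour frames")
    vals = _perturbation_block(T) + _perturbation_block(P)
    return np.asarray(vals)


# shimmer: the amplitude block trades the two log-local slots for the
# classical dB variants and APQ11, and drops DDP for DDA symmetry

def _shimmer_db(seq: np.ndarray, agg) -> float:
    return float(agg(np.abs(20.0 * np.log10(seq[1:] / seq[:-1]))))


def _amp_block(seq: np.ndarray, with_log: bool) -> tuple[list[float], list[str]]:
    vals = [
        _local(seq, np.mean),
        _local(seq, np.median),
        _shimmer_db(seq, np.mean),
        _shimmer_db(seq, np.median),
        _ppq(seq, 3, np.mean),       # APQ3
        _ppq(seq, 5, np.mean),       # APQ5
        _ppq(seq, 11, np.mean),      # APQ11
        _ddp(seq),                   # DDA
    ]
    names = ["local_mean", "local_median", "db_mean", "db_median",
             "apq3", "apq5", "apq11", "dda"]
    if with_log:
        vals.append(_log_local(seq, np.mean))
        names.append("log_local_mean")
    m, s = _tkeo_stats(seq)
    vals += [m, s]
    names += ["tkeo_mean", "tkeo_sd"]
    return vals, names


def shimmer_names() -> list[str]:
    _, amp_names = _amp_block(np.ones(16) + np.linspace(0, 0.1, 16), True)
    _, en_names = _amp_block(np.ones(16) + np.linspace(0, 0.1, 16), False)
    return [f"shimmer.cycle.{s}" for s in amp_names] + \
           [f"shimmer.energy.{s}" for s in en_names]


def shimmer_family(c: CycleSequence, segment: Phonation) -> np.ndarray:
    """21 amplitude-perturbation measures from cycle peaks and frame energies."""
    A = np.asarray(c.amplitudes, dtype=float)
    if len(A) < MIN_CYCLES:
        raise FeatureFlagged("shimmer", f"only {len(A)} cycles (<{MIN_CYCLES})")
    if np.any(A <= 0):
        raise FeatureFlagged("shimmer", "non-positive cycle amplitude")
    frames = frame_signal(segment.samples, int(0.025 * segment.fs),
                          int(0.010 * segment.fs))
    E = np.sqrt(np.mean(frames**2, axis=1))
    E = E[E > 0]
    if len(E) < MIN_CYCLES:
        raise FeatureFlagged("shimmer", "too few energetic frames")
    va, _ = _amp_block(A, with_log=True)
    ve, _ = _amp_block(E, with_log=False)
    return np.asarray(va + ve)


def gq_names() -> list[str]:
    return ["gq.cv_median", "gq.range90", "gq.deviant_fraction"]


def gq_family(c: CycleSequence) -> np.ndarray:
    """3 glottis-quotient statistics of vocal-fold cycle duration change."""
    T = np.asarray(c.periods, dtype=float)
    if len(T) < MIN_CYCLES:
        raise FeatureFlagged("gq", f"only {len(T)} periods (<{MIN_CYCLES})")
    med = float(np.median(T))
    v1 = float(np.std(T) / med)
    v2 = float((np.percentile(T, 95) - np.percentile(T, 5)) / med)
    v3 = float(np.mean(np.abs(T - med) / med > 0.05))
    return np.asarray([v1, v2, v3])
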