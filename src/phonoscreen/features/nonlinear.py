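"""Nonlinear time-series measures: DFA and RPDE.

Detrended fluctuation analysis quantifies the stochastic self-similarity of
the turbulent-noise component; recurrence period density entropy quantifies
the uncertainty of the dominant period in a time-delay-embedded state
space.  Both are normalised to [0, 1] for use as dysphonia measures.
"""

from __future__ import annotations

import numpy as np

from ..core import FeatureFlagged, Phonation

_EPS = 1e-12


def dfa_names() -> list[str]:
    return ["dfa.alpha_norm"]


def dfa_alpha(x: np.ndarray, box_min: int = 50, box_max: int = 1000,
              n_boxes: int = 15) -> float:
    """Raw DFA scaling exponent (first-order detrending)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * box_max:
        box_max = max(len(x) // 4, 2 * box_min)
    y = np.cumsum(x - x.mean())
    sizes = np.unique(np.logspace(np.log10(box_min), np.log10(box_max),
                                  n_boxes).astype(int))
    fl = []
    t_full = np.arange(len(y))
    for L in sizes:
        n_seg = len(y) // L
        seg = y[: n_seg * L].reshape(n_seg, L)
        t = np.arange(L)
        # per-segment linear detrend via closed-form least squares
        tm = t.mean()
        denom = np.sum((t - tm) ** 2)
        slope = (seg @ (t - tm)) / denom
        inter = seg.mean(axis=1) - slope * tm
        resid = seg - (inter[:, None] + slope[:, None] * t)
        fl.append(np.sqrt(np.mean(resid**2)))
    fl = np.asarray(fl)
    if np.any(fl <= 0):
        raise FeatureFlagged("dfa", "degenerate fluctuation (constant signal)")
    return float(np.polyfit(np.log10(sizes), np.log10(fl), 1)[0])


def dfa(segment: Phonation) -> np.ndarray:
    """Normalised DFA exponent alpha' = 1 / (1 + exp(-alpha))."""
    if len(segment.samples) < 4000:
        raise FeatureFlagged("dfa", "fewer than 4000 samples")
    if np.allclose(segment.samples, segment.samples[0]):
        raise FeatureFlagged("dfa", "constant signal")
    alpha = dfa_alpha(segment.samples)
    return np.asarray([1.0 / (1.0 + np.exp(-alpha))])


def rpde_names() -> list[str]:
    return ["rpde.rpde"]


def _return_times(x: np.ndarray, m: int, tau: int, eps: float,
                  t_max: int, stride: int) -> np.ndarray:
    """First-return times into an eps-ball after leaving it, per anchor."""
    n_emb = len(x) - (m - 1) * tau
    X = np.stack([x[k * tau: k * tau + n_emb] for k in range(m)], axis=1)
    anchors = np.arange(0, n_emb - t_max - 1, stride)
    if len(anchors) == 0:
        return np.empty(0, dtype=int)
    # D2[t, i] = squared distance between anchor i and the point t steps later
    D2 = np.empty((t_max, len(anchors)))
    for t in range(1, t_max + 1):
        diff = X[anchors + t] - X[anchors]
        D2[t - 1] = np.einsum("ij,ij->i", diff, diff)
    inside = D2 < eps * eps
    exited = np.maximum.accumulate(~inside, axis=0)
    # first re-entry strictly after the first exit
    prev_exited = np.vstack([np.zeros((1, inside.shape[1]), dtype=bool),
                             exited[:-1]])
    reentry = inside & prev_exited
    has = reentry.any(axis=0)
    t_first = np.argmax(reentry, axis=0) + 1
    return t_first[has]


def rpde(segment: Phonation, m: int = 4, tau: int = 7,
         eps_factor: float = 0.12, t_max: int | None = None,
         stride: int = 4) -> np.ndarray:
    """Recurrence period density entropy, normalised to [0, 1].

    Embedding dimension 4, delay 7 samples (tuned for 8 kHz sustained
    vowels), ball radius 0.12 x signal SD; the histogram of first return
    times up to ``t_max`` (default one 50 Hz period) is entropy-scored.
    """
    x = np.asarray(segment.samples, dtype=float)
    if len(x) < 4000:
        raise FeatureFlagged("rpde", "fewer than 4000 samples")
    sd = x.std()
    if sd <= _EPS:
        raise FeatureFlagged("rpde", "constant signal")
    x = x / sd
    if t_max is None:
        t_max = int(round(segment.fs / 50.0))
    times = _return_times(x, m, tau, eps_factor, t_max, stride)
    if times.size == 0:
        raise FeatureFlagged("rpde", "no recurrences found")
    counts = np.bincount(times, minlength=t_max + 1)[1:]
    p = counts / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum() / np.log(t_max))
    return np.asarray([h])


def rpde_from_return_times(times: np.ndarray, t_max: int) -> float:
    """Entropy step alone (exposed for oracle tests on known densities)."""
    counts = np.bincount(np.asarray(times, dtype=int), minlength=t_max + 1)[1:]
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(t_max))
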