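"""Automated phonation quality screening and stationary-segment selection.

Recordings with too little voicing, clipping, low SNR or insufficient
duration are excluded before feature extraction; for the survivors the
least-fluctuating 2 s stretch of the 10 ms F0 contour defines the analysis
segment used by every dysphonia measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dsp import fft_bandpass
from .core import Phonation, PhonoscreenError
from .pitch import F0Contour, estimate_f0_contour


@dataclass(frozen=True)
class QCThresholds:
    """Screening thresholds (reconstructed defaults, all configurable)."""

    min_duration: float = 2.5          # s
    min_voiced_fraction: float = 0.6
    max_clipping_fraction: float = 0.01
    min_snr_db: float = 10.0


@dataclass
class QCReport:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    voiced_fraction: float = float("nan")
    clipping_fraction: float = float("nan")
    snr_estimate: float = float("nan")

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


@dataclass
class SegmentWindow:
    """A 2 s analysis window with its F0 dispersion score."""

    start: float
    end: float
    f0_dispersion: float


def estimate_snr(p: Phonation, contour: F0Contour) -> float:
    """Crude deterministic SNR: voiced-band energy over >3 kHz residual.

    The ratio is normalised by relative bandwidth so that broadband noise at
    0 dB overall SNR scores near 0 dB.
    """
    hi_edge = p.fs / 2.0
    lo = fft_bandpass(p.samples, p.fs, 300.0, 3000.0)
    hi = fft_bandpass(p.samples, p.fs, 3000.0, hi_edge)
    e_lo = float(np.mean(lo**2))
    e_hi = float(np.mean(hi**2))
    if e_hi <= 0:
        return np.inf if e_lo > 0 else 0.0
    bw_ratio = (hi_edge - 3000.0) / 2700.0
    return float(10.0 * np.log10(e_lo / e_hi * bw_ratio + 1e-12))


def screen_quality(p: Phonation, thresholds: QCThresholds = QCThresholds(),
                   contour: F0Contour | None = None) -> QCReport:
    """Deterministic pass/fail screening with all failing reasons listed."""
    reasons: list[str] = []
    x = p.samples
    if len(x) == 0 or not np.all(np.isfinite(x)):
        return QCReport(passed=False, reasons=["invalid_audio"])

    if p.duration < thresholds.min_duration:
        reasons.append("too_short")

    # clipping is amplitude-referenced by design (full scale = 1)
    clipping_fraction = float(np.mean(np.abs(x) >= 0.999))
    if clipping_fraction > thresholds.max_clipping_fraction:
        reasons.append("clipped")

    if contour is None:
        contour = estimate_f0_contour(p)
    voiced_fraction = float(contour.voiced.mean()) if len(contour.f0) else 0.0
    if voiced_fraction < thresholds.min_voiced_fraction:
        reasons.append("unvoiced")

    snr = estimate_snr(p, contour)
    if snr < thresholds.min_snr_db:
        reasons.append("low_snr")

    return QCReport(
        passed=not reasons,
        reasons=reasons,
        voiced_fraction=voiced_fraction,
        clipping_fraction=clipping_fraction,
        snr_estimate=snr,
    )


def select_stationary_segment(p: Phonation, f0: F0Contour,
                              window_s: float = 2.0) -> SegmentWindow:
    """Return the 2 s window minimising the SD of F0 on the 10 ms grid.

    Candidate windows are aligned to the contour grid and must be fully
    voiced; ties break toward the earliest window.
    """
    n_frames = int(round(window_s / 0.010))
    voiced = f0.voiced
    if len(f0.f0) < n_frames:
        raise PhonoscreenError("recording shorter than the analysis window")

    best: tuple[float, int] | None = None
    for s in range(0, len(f0.f0) - n_frames + 1):
        w = f0.f0[s: s + n_frames]
        if not np.all(voiced[s: s + n_frames]):
            continue
        sd = float(np.std(w))
        if best is None or sd < best[0] - 1e-15:
            best = (sd, s)
    if best is None:
        raise PhonoscreenError(
            "no fully voiced 2 s window (recording should have failed QC)")
    sd, s = best
    start = float(f0.times[s])
    return SegmentWindow(start=start, end=start + window_s, f0_dispersion=sd)
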