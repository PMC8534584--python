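"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class PhonoscreenError(Exception):
    """Base class for package errors."""


class InvalidAudioError(PhonoscreenError):
    """Raised when an audio file cannot be decoded as PCM WAV."""


class FeatureFlagged(PhonoscreenError):
    """Raised when a feature family cannot be computed on a recording.

    Carries the family name so callers can flag the recording instead of
    silently imputing values.
    """

    def __init__(self, family: str, reason: str):
        super().__init__(f"{family}: {reason}")
        self.family = family
        self.reason = reason


@dataclass
class Phonation:
    """A mono sustained-vowel recording.

    ``samples`` are real-valued in [-1, 1]; ``fs`` is the sampling rate in Hz.
    ``meta`` carries per-recording metadata (participant id, label, age,
    gender, ...).
    """

    samples: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Phonation samples must be 1-D (mono)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def crop(self, start: float, end: float) -> "Phonation":
        """Return the sub-recording on [start, end) seconds."""
        i0 = int(round(start * self.fs))
        i1 = int(round(end * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.samples))
        return Phonation(self.samples[i0:i1].copy(), self.fs, dict(self.meta))
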