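"""Shared fixtures: synthetic phonations rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phonoscreen.core import Phonation
from phonoscreen.pitch import estimate_f0_contour
from phonoscreen.synth import (ChannelSpec, PhonationSpec,
                               apply_telephone_channel, synthesize_phonation)


def telephone_phonation(**kwargs):
    """Synthesize at studio rate and degrade through the default channel."""
    spec = PhonationSpec(**kwargs)
    p, gt = synthesize_phonation(spec)
    return apply_telephone_channel(p), gt


@pytest.fixture(scope="session")
def clean_phonation():
    """Zero-perturbation 150 Hz telephone phonation with ground truth."""
    return telephone_phonation(base_f0=150.0, seed=11)


@pytest.fixture(scope="session")
def perturbed_phonation():
    """Moderately jittered/shimmered/noisy telephone phonation."""
    return telephone_phonation(base_f0=150.0, jitter_level=0.01,
                               shimmer_level=0.03, noise_level=0.02, seed=42)


@pytest.fixture(scope="session")
def clean_contour(clean_phonation):
    p, _ = clean_phonation
    return estimate_f0_contour(p)


@pytest.fixture(scope="session")
def clean_segment(clean_phonation):
    p, _ = clean_phonation
    return p.crop(0.5, 2.5)


@pytest.fixture(scope="session")
def white_noise():
    rng = np.random.default_rng(7)
    return Phonation(0.3 * rng.standard_normal(16000), 8000.0)


@pytest.fixture(scope="session")
def sine_160hz():
    """160 Hz sine commensurate with 8 kHz (period exactly 50 samples)."""
    t = np.arange(16000) / 8000.0
    return Phonation(0.5 * np.sin(2 * np.pi * 160.0 * t), 8000.0)
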