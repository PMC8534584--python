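"""Synthetic sustained /a/ phonations with known perturbation ground truth.

The generator produces a Rosenberg-pulse glottal source train whose
cycle-to-cycle periods and peak amplitudes are perturbed by i.i.d. Gaussian
factors (jitter and shimmer), optionally modulated by a slow F0 tremor,
mixed with formant-filtered aspiration noise, and shaped by a cascade of
second-order vowel-/a/ resonators.  A telephone-network channel model
(resample to 8 kHz, 300-3400 Hz band-pass, 16-bit quantisation, optional
additive channel noise) degrades the studio-rate signal to the quality of
recordings collected over standard telephone lines.

Every waveform is bit-reproducible from its spec + seed, and the realised
cycle times, periods and amplitudes are returned as ground truth so that
downstream perturbation measures can be validated against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import Phonation, PhonoscreenError

#: conventional adult /a/ formant centres and bandwidths (Hz)
DEFAULT_FORMANTS: tuple[tuple[float, float], ...] = (
    (710.0, 80.0),
    (1100.0, 90.0),
    (2540.0, 120.0),
)


@dataclass(frozen=True)
class PhonationSpec:
    """Parameters of one synthetic sustained phonation.

    jitter_level and shimmer_level are the SD of the relative cycle-to-cycle
    period / peak-amplitude perturbation; noise_level is the aspiration-noise
    RMS relative to the voiced-signal RMS; tremor is a slow sinusoidal F0
    modulation of depth ``tremor_extent`` Hz at ``tremor_rate`` Hz.
    """

    duration: float = 5.0
    base_f0: float = 150.0
    jitter_level: float = 0.0
    shimmer_level: float = 0.0
    noise_level: float = 0.0
    tremor_extent: float = 0.0
    tremor_rate: float = 5.0
    formants: tuple[tuple[float, float], ...] = DEFAULT_FORMANTS
    source_fs: float = 44100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (50.0 <= self.base_f0 <= 500.0):
            raise ValueError("base_f0 must lie in [50, 500] Hz")
        for name in ("jitter_level", "shimmer_level", "noise_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ChannelSpec:
    """Standard-telephone-network degradation parameters."""

    target_fs: float = 8000.0
    bit_depth: int = 16
    passband: tuple[float, float] = (300.0, 3400.0)
    channel_snr: float | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.passband[1] >= self.target_fs / 2:
            raise ValueError("passband high edge must be below Nyquist")
        if self.passband[0] >= self.passband[1]:
            raise ValueError("passband low edge must be below high edge")


@dataclass
class GroundTruth:
    """Realised source parameters of a synthetic phonation."""

    cycle_times: np.ndarray      # glottal cycle onsets (s)
    periods: np.ndarray          # realised T_i (s), len = len(cycle_times) - 1
    amplitudes: np.ndarray       # realised A_i per cycle, len = len(periods)
    f0_track: np.ndarray         # instantaneous F0 (Hz) on a 10 ms grid
    f0_times: np.ndarray

    def realized_jitter(self) -> float:
        """SD(T_i)/mean(T_i) of the realised period sequence."""
        return float(np.std(self.periods) / np.mean(self.periods))

    def realized_shimmer(self) -> float:
        return float(np.std(self.amplitudes) / np.mean(self.amplitudes))

    def jitter_local(self) -> float:
        """mean |T_i - T_{i+1}| / mean T of the realised periods."""
        t = self.periods
        return float(np.mean(np.abs(np.diff(t))) / np.mean(t))

    def shimmer_local(self) -> float:
        a = self.amplitudes
        return float(np.mean(np.abs(np.diff(a))) / np.mean(a))


def _rosenberg_pulse(n_cycle: int) -> np.ndarray:
    """One cycle of the Rosenberg glottal flow derivative.

    The cycle starts at the glottal closure (the sharp flow fall), so the
    dominant excitation event sits exactly at the cycle onset and realised
    excitation periods equal the generated T_i.
    """
    n_cycle = max(n_cycle, 4)
    n_close = max(int(round(0.3 * n_cycle)), 2)
    n_open = n_cycle - n_close
    t1 = np.arange(n_close) / n_close
    fall = (1.0 - t1) ** 2
    t2 = np.arange(n_open) / n_open
    rise = 3.0 * t2**2 - 2.0 * t2**3
    g = np.concatenate([fall, rise])
    # differentiate: acoustic excitation is the flow derivative
    return np.diff(g, prepend=1.0)


def _formant_cascade(x: np.ndarray, fs: float,
                     formants: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Pass ``x`` through cascaded two-pole resonators (unity gain at centre)."""
    y = x
    for fc, bw in formants:
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * fc / fs
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        # normalise for unity gain at the centre frequency
        w = np.exp(1j * theta)
        gain = abs(1.0 / (a[0] + a[1] / w + a[2] / w**2))
        y = sps.lfilter([1.0 / gain], a, y)
    return y


def synthesize_phonation(spec: PhonationSpec) -> tuple[Phonation, GroundTruth]:
    """Render a sustained /a/ phonation and its perturbation ground truth.

    Cycle i has period T_i = (1/f0(t_i)) * (1 + jitter_level * eps_i) and
    peak amplitude A_i = 1 + shimmer_level * eta_i with eps, eta standard
    normal; aspiration noise is added at ``noise_level`` relative RMS.
    """
    fs = spec.source_fs
    rng = np.random.default_rng(spec.seed)

    def inst_f0(t: float | np.ndarray) -> float | np.ndarray:
        return spec.base_f0 + spec.tremor_extent * np.sin(
            2.0 * math.pi * spec.tremor_rate * t)

    # --- realise the cycle sequence in continuous time -------------------
    times = [0.0]
    periods: list[float] = []
    while True:
        t = times[-1]
        T = (1.0 / inst_f0(t)) * (1.0 + spec.jitter_level * rng.standard_normal())
        T = max(T, 1.0 / 500.0 * 0.5)   # guard against pathological draws
        if t + T > spec.duration:
            break
        periods.append(T)
        times.append(t + T)
    if len(periods) < 3:
        raise PhonoscreenError("duration too short: fewer than 3 glottal cycles")
    amps = 1.0 + spec.shimmer_level * rng.standard_normal(len(periods))
    amps = np.clip(amps, 0.05, None)

    # --- render the glottal source train ---------------------------------
    n = int(round(spec.duration * fs))
    source = np.zeros(n)
    for t0, T, A in zip(times[:-1], periods, amps):
        i0 = int(round(t0 * fs))
        pulse = _rosenberg_pulse(int(round(T * fs)))
        i1 = min(i0 + len(pulse), n)
        source[i0:i1] += A * pulse[: i1 - i0]

    voiced = _formant_cascade(source, fs, spec.formants)

    if spec.noise_level > 0:
        noise = rng.standard_normal(n)
        noise = _formant_cascade(noise, fs, spec.formants)
        noise *= spec.noise_level * np.std(voiced) / np.std(noise)
        voiced = voiced + noise

    peak = np.max(np.abs(voiced))
    if peak > 0:
        voiced = voiced * (0.5 / peak)

    f0_times = np.arange(0.0, spec.duration, 0.010)
    gt = GroundTruth(
        cycle_times=np.asarray(times),
        periods=np.asarray(periods),
        amplitudes=amps,
        f0_track=np.asarray(inst_f0(f0_times), dtype=float),
        f0_times=f0_times,
    )
    meta = {"synthetic": True, "seed": spec.seed, "base_f0": spec.base_f0,
            "jitter_level": spec.jitter_level,
            "shimmer_level": spec.shimmer_level,
            "noise_level": spec.noise_level}
    return Phonation(voiced, fs, meta), gt


def apply_telephone_channel(p: Phonation, ch: ChannelSpec = ChannelSpec()) -> Phonation:
    """Degrade a studio-rate phonation to telephone quality.

    Resample to ``target_fs``, zero-phase band-pass to the passband,
    quantise to ``bit_depth`` bits and optionally add white channel noise at
    ``channel_snr`` dB.  Output duration matches input within one sample.
    """
    if p.fs < 2.0 * ch.passband[1]:
        raise PhonoscreenError("input sampling rate too low for the passband")
    x = p.samples
    if p.fs != ch.target_fs:
        g = math.gcd(int(round(p.fs)), int(round(ch.target_fs)))
        up = int(round(ch.target_fs)) // g
        down = int(round(p.fs)) // g
        x = sps.resample_poly(x, up, down)
    sos = sps.butter(4, ch.passband, btype="bandpass",
                     fs=ch.target_fs, output="sos")
    x = sps.sosfiltfilt(sos, x)

    if ch.channel_snr is not None:
        sig_rms = np.std(x)
        rng = np.random.default_rng(int(p.meta.get("seed", 0)) + 7919)
        noise = rng.standard_normal(len(x))
        noise *= sig_rms / (np.std(noise) * 10.0 ** (ch.channel_snr / 20.0))
        x = x + noise

    # quantise as a PCM codec would
    full_scale = 2 ** (ch.bit_depth - 1)
    x = np.clip(x, -1.0, 1.0 - 1.0 / full_scale)
    x = np.round(x * full_scale) / full_scale

    meta = dict(p.meta)
    meta["channel"] = {"target_fs": ch.target_fs, "bit_depth": ch.bit_depth,
                       "passband": ch.passband, "channel_snr": ch.channel_snr}
    return Phonation(x, ch.target_fs, meta)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class Gaussian parameter distributions over PhonationSpec values."""

    jitter_mean: float = 0.006
    jitter_sd: float = 0.002
    shimmer_mean: float = 0.02
    shimmer_sd: float = 0.008
    noise_mean: float = 0.02
    noise_sd: float = 0.01
    f0_mean: float = 150.0
    f0_sd: float = 25.0
    age_mean: float = 49.19
    age_sd: float = 15.89
    male_fraction: float = 0.546


#: default class-conditional distributions: the positive (PwP) class carries
#: roughly doubled perturbation means; ages/sex follow the cohort table.
DEFAULT_CONTROL = ClassDistribution()
DEFAULT_PD = ClassDistribution(
    jitter_mean=0.012, jitter_sd=0.004,
    shimmer_mean=0.04, shimmer_sd=0.015,
    noise_mean=0.04, noise_sd=0.02,
    f0_mean=145.0, f0_sd=30.0,
    age_mean=62.65, age_sd=12.03,
    male_fraction=0.525,
)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort mirroring the study's structure."""

    n_pd_recordings: int = 1987
    n_control_recordings: int = 9955
    n_pd_participants: int = 1078
    n_control_participants: int = 5453
    pd_distribution: ClassDistribution = DEFAULT_PD
    control_distribution: ClassDistribution = DEFAULT_CONTROL
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd_recordings < self.n_pd_participants:
            raise ValueError("PD recordings must be >= PD participants")
        if self.n_control_recordings < self.n_control_participants:
            raise ValueError("control recordings must be >= control participants")


@dataclass
class CohortRecord:
    """One cohort entry: metadata plus a lazily renderable phonation spec."""

    spec: PhonationSpec
    meta: dict

    def render(self) -> tuple[Phonation, GroundTruth]:
        p, gt = synthesize_phonation(self.spec)
        p.meta.update(self.meta)
        return p, gt


def _sample_specs(rng: np.random.Generator, dist: ClassDistribution,
                  n_recordings: int, n_participants: int, label: int,
                  id_prefix: str, duration: float) -> list[CohortRecord]:
    # every participant gets one recording, the surplus is spread uniformly
    owners = np.concatenate([
        np.arange(n_participants),
        rng.integers(0, n_participants, n_recordings - n_participants),
    ])
    ages = np.clip(rng.normal(dist.age_mean, dist.age_sd, n_participants), 18, 95)
    genders = np.where(rng.random(n_participants) < dist.male_fraction, "M", "F")
    records = []
    for k, owner in enumerate(owners):
        spec = PhonationSpec(
            duration=duration,
            base_f0=float(np.clip(rng.normal(dist.f0_mean, dist.f0_sd), 75, 320)),
            jitter_level=float(np.clip(rng.normal(dist.jitter_mean, dist.jitter_sd), 0, 0.1)),
            shimmer_level=float(np.clip(rng.normal(dist.shimmer_mean, dist.shimmer_sd), 0, 0.3)),
            noise_level=float(np.clip(rng.normal(dist.noise_mean, dist.noise_sd), 0, 0.5)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records.append(CohortRecord(spec=spec, meta={
            "file": f"{id_prefix}{k:05d}.wav",
            "participant_id": f"{id_prefix}P{owner:05d}",
            "label": label,
            "age": float(ages[owner]),
            "gender": str(genders[owner]),
        }))
    return records


def generate_cohort(cs: CohortSpec = CohortSpec(), render: bool = False):
    """Generate a labelled synthetic cohort.

    Returns a list of :class:`CohortRecord` (label 1 = PwP, 0 = control).
    With ``render=True`` each entry is materialised as
    ``(Phonation, metadata, GroundTruth)`` — intended for small cohorts;
    Table-1-scale cohorts should stay lazy and be rendered on demand.
    """
    rng = np.random.default_rng(cs.seed)
    records = _sample_specs(rng, cs.pd_distribution, cs.n_pd_recordings,
                            cs.n_pd_participants, 1, "pd", cs.duration)
    records += _sample_specs(rng, cs.control_distribution,
                             cs.n_control_recordings,
                             cs.n_control_participants, 0, "ct", cs.duration)
    if not render:
        return records
    out = []
    for rec in records:
        p, gt = rec.render()
        out.append((p, rec.meta, gt))
    return out
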