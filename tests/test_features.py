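"""The dysphonia feature battery: counts, worked examples, invariants."""

import numpy as np
import pytest

from phonoscreen.core import FeatureFlagged, Phonation
from phonoscreen.features import (FAMILY_COUNTS, extract_all, family_index,
                                  feature_names)
from phonoscreen.features.contour import (NormativeF0Table,
                                          f0_related_family, ppe,
                                          wavelet_family)
from phonoscreen.features.emd import emd, emd_er_family
from phonoscreen.features.nonlinear import dfa, dfa_alpha, rpde, rpde_from_return_times
from phonoscreen.features.noise import gne_family, hnr_nhr, vfer_family
from phonoscreen.features.perturbation import (gq_family, jitter_family,
                                               shimmer_family)
from phonoscreen.features.spectral import mfcc_family
from phonoscreen.pitch import CycleSequence, F0Contour, estimate_f0_contour

from conftest import telephone_phonation


def make_cycles(periods, amplitudes=None):
    periods = np.asarray(periods, dtype=float)
    marks = np.concatenate([[0.0], np.cumsum(periods)])
    if amplitudes is None:
        amplitudes = np.ones(len(periods))
    return CycleSequence(cycle_marks=marks, periods=periods,
                         amplitudes=np.asarray(amplitudes, dtype=float))


def constant_contour(f0=150.0, n=200):
    return F0Contour(times=np.arange(n) * 0.010, f0=np.full(n, float(f0)),
                     strength=np.ones(n))


class TestManifest:
    def test_family_counts_total_304(self):
        names = feature_names()
        assert len(names) == 304
        assert len(set(names)) == 304
        for fam, count in FAMILY_COUNTS.items():
            assert sum(1 for n in names if n.startswith(fam + ".")) == count

    def test_family_index_covers_vector(self):
        idx = family_index()
        covered = sorted(i for s in idx.values() for i in range(s.start, s.stop))
        assert covered == list(range(304))

    def test_packaged_manifest_matches_generated(self):
        import importlib.resources as res
        text = (res.files("phonoscreen") / "data" / "manifest.txt").read_text()
        listed = [ln.split("\t")[1] for ln in text.splitlines()
                  if ln and not ln.startswith("#")]
        assert listed == feature_names()


class TestJitterFamily:
    def test_constant_periods_all_zero(self):
        c = make_cycles(np.full(100, 0.005))
        vals = jitter_family(c, constant_contour())
        assert vals.shape == (28,)
        assert np.allclose(vals, 0.0)

    def test_hand_computed_local_jitter(self):
        periods_ms = [5.0, 5.1, 4.9, 5.0, 5.2]
        c = make_cycles(np.asarray(periods_ms * 4) / 1000.0)
        vals = jitter_family(c, constant_contour())
        expected = np.mean(np.abs(np.diff(np.asarray(periods_ms * 4)))) / np.mean(periods_ms)
        assert vals[0] == pytest.approx(expected)
        # the spec's 5-period worked value for jitter_local
        five = np.asarray(periods_ms)
        assert float(np.mean(np.abs(np.diff(five))) / np.mean(five)) == \
            pytest.approx(0.0297619, abs=1e-6)

    def test_too_few_cycles_flagged(self):
        with pytest.raises(FeatureFlagged):
            jitter_family(make_cycles(np.full(5, 0.005)), constant_contour())


class TestShimmerFamily:
    def test_constant_amplitudes_cycle_block_zero(self, clean_segment):
        c = make_cycles(np.full(100, 0.005))
        vals = shimmer_family(c, clean_segment)
        assert vals.shape == (21,)
        assert np.allclose(vals[:11], 0.0)   # cycle-amplitude block

    def test_hand_computed_local_shimmer(self, clean_segment):
        amps = [1.0, 1.1, 0.9, 1.0] * 5
        c = make_cycles(np.full(len(amps), 0.005), amps)
        vals = shimmer_family(c, clean_segment)
        assert vals[0] == pytest.approx(
            np.mean(np.abs(np.diff(amps))) / np.mean(amps))
        four = np.asarray([1.0, 1.1, 0.9, 1.0])
        assert float(np.mean(np.abs(np.diff(four))) / np.mean(four)) == \
            pytest.approx(0.13333, abs=1e-4)

    def test_nonpositive_amplitude_flagged(self, clean_segment):
        amps = np.ones(20)
        amps[3] = 0.0
        with pytest.raises(FeatureFlagged):
            shimmer_family(make_cycles(np.full(20, 0.005), amps), clean_segment)


class TestGQFamily:
    def test_constant_periods_zero(self):
        assert np.allclose(gq_family(make_cycles(np.full(50, 0.005))), 0.0)

    def test_alternating_periods_full_deviation(self):
        periods = np.tile([0.0045, 0.0055], 25)
        vals = gq_family(make_cycles(periods))
        assert vals[2] == pytest.approx(1.0)


class TestHNR:
    def test_pure_sine_high_hnr(self, sine_160hz):
        c = estimate_f0_contour(sine_160hz)
        vals = hnr_nhr(sine_160hz, c)
        assert vals.shape == (4,)
        assert vals[0] >= 30.0

    def test_white_noise_low_hnr(self, white_noise):
        vals = hnr_nhr(white_noise, constant_contour())
        assert vals[0] <= 3.0


class TestGNE:
    def test_clean_phonation_high_gne(self, clean_segment):
        vals = gne_family(clean_segment)
        assert vals.shape == (6,)
        assert vals[0] >= 0.8

    def test_noise_below_phonation(self, clean_segment, white_noise):
        assert gne_family(white_noise)[0] < gne_family(clean_segment)[0]


class TestVFER:
    def test_white_noise_matches_bandwidth_ratio(self, white_noise):
        vals = vfer_family(white_noise)
        assert vals.shape == (9,)
        assert vals[6] == pytest.approx(2.5 / 1.5, rel=0.10)

    def test_bandlimited_phonation_favors_low_band(self, clean_segment):
        from phonoscreen._dsp import fft_bandpass
        bl = Phonation(fft_bandpass(clean_segment.samples, 8000.0, 300.0,
                                    2000.0), 8000.0)
        assert vfer_family(bl)[6] >= 10.0


class TestEMD:
    def test_two_tone_ratio_above_one(self):
        t = np.arange(16000) / 8000.0
        x = np.sin(2 * np.pi * 100.0 * t) + 0.05 * np.sin(2 * np.pi * 3000.0 * t)
        vals = emd_er_family(Phonation(0.4 * x, 8000.0))
        assert vals.shape == (6,)
        assert vals[1] > 1.0

    def test_clean_above_noise(self, clean_segment, white_noise):
        assert emd_er_family(clean_segment)[1] > emd_er_family(white_noise)[1]

    def test_imfs_reconstruct_signal(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000)
        imfs = emd(x)
        assert np.allclose(np.sum(imfs, axis=0), x, atol=1e-8)


class TestMFCC:
    def test_gain_changes_only_c0(self, clean_segment):
        a = mfcc_family(clean_segment)
        b = mfcc_family(Phonation(10.0 * clean_segment.samples, 8000.0))
        assert a.shape == (39,)
        assert abs(b[0] - a[0]) > 1.0
        assert np.max(np.abs(b[1:13] - a[1:13])) < 1e-6

    def test_stationary_input_zero_deltas(self):
        # 1 kHz: the window main lobes at +-f0 do not overlap, so framewise
        # spectra are phase-independent and the cepstra are constant
        t = np.arange(16000) / 8000.0
        p = Phonation(0.5 * np.sin(2 * np.pi * 1000.0 * t), 8000.0)
        vals = mfcc_family(p)
        assert np.max(np.abs(vals[13:])) < 1e-3


class TestF0Related:
    def test_at_normative_mean(self):
        c = constant_contour(120.0)
        vals = f0_related_family(c, 60.0, "M")
        assert vals[0] == pytest.approx(0.0, abs=1e-9)
        assert vals[1] == pytest.approx(1.0, abs=1e-9)

    def test_one_sd_above(self):
        f0 = 120.0 * np.exp(0.15)
        vals = f0_related_family(constant_contour(f0), 60.0, "M")
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        assert vals[1] == pytest.approx(0.3173, abs=1e-3)

    def test_missing_gender_flagged(self):
        with pytest.raises(FeatureFlagged):
            f0_related_family(constant_contour(), 60.0, "X")


class TestWavelet:
    def test_output_length_and_constant_contour(self):
        vals = wavelet_family(constant_contour(n=256))
        assert vals.shape == (182,)
        names = feature_names()
        le = [v for n, v in zip(names[family_index()["wavelet"]], vals)
              if n.endswith(".log_energy") and ".d" in n]
        assert all(v < -8.0 for v in le)   # detail energies ~ 0 (log10 scale)

    def test_tremor_energy_in_matching_band(self):
        # 5 Hz tremor on the 100 Hz contour grid: level-4 detail band
        # covers 3.1-6.25 Hz
        n = 512
        f0 = 150.0 + 5.0 * np.sin(2 * np.pi * 5.0 * np.arange(n) * 0.010)
        c = F0Contour(times=np.arange(n) * 0.010, f0=f0, strength=np.ones(n))
        vals = wavelet_family(c)
        names = feature_names()[family_index()["wavelet"]]
        fracs = {nm: v for nm, v in zip(names, vals)
                 if nm.startswith("wavelet.f0.") and nm.endswith("energy_fraction")}
        best = max(fracs, key=fracs.get)
        assert best == "wavelet.f0.d4.energy_fraction"


class TestPPE:
    def test_constant_contour_zero(self):
        assert ppe(constant_contour())[0] == 0.0

    def test_uniform_residuals_near_one(self):
        rng = np.random.default_rng(0)
        f0 = 150.0 * 2.0 ** (rng.uniform(-12, 12, 10000) / 12.0)
        c = F0Contour(times=np.arange(10000) * 0.010, f0=f0,
                      strength=np.ones(10000))
        assert ppe(c)[0] >= 0.95

    def test_linear_drift_whitened_away(self):
        f0 = 150.0 * 2.0 ** (np.linspace(0.0, 6.0, 500) / 12.0)
        c = F0Contour(times=np.arange(500) * 0.010, f0=f0,
                      strength=np.ones(500))
        assert ppe(c)[0] <= 0.1

    def test_bounded_unit_interval(self, clean_phonation):
        p, _ = clean_phonation
        v = ppe(estimate_f0_contour(p))[0]
        assert 0.0 <= v <= 1.0


class TestDFA:
    def test_white_noise_half(self):
        rng = np.random.default_rng(3)
        alpha = dfa_alpha(rng.standard_normal(16000))
        assert alpha == pytest.approx(0.5, abs=0.05)

    def test_random_walk_three_halves(self):
        rng = np.random.default_rng(4)
        alpha = dfa_alpha(np.cumsum(rng.standard_normal(16000)))
        assert alpha == pytest.approx(1.5, abs=0.1)

    def test_scale_invariance(self, white_noise):
        a = dfa_alpha(white_noise.samples)
        b = dfa_alpha(123.0 * white_noise.samples)
        assert a == pytest.approx(b, abs=1e-9)

    def test_normalisation(self, white_noise):
        v = dfa(white_noise)[0]
        alpha = dfa_alpha(white_noise.samples)
        assert v == pytest.approx(1.0 / (1.0 + np.exp(-alpha)))


class TestRPDE:
    def test_strictly_periodic_zero(self, sine_160hz):
        assert rpde(sine_160hz)[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_density_is_one(self):
        t_max = 100
        times = np.tile(np.arange(1, t_max + 1), 5)
        assert rpde_from_return_times(times, t_max) == pytest.approx(1.0)

    def test_noise_above_clean_phonation(self, clean_segment, white_noise):
        assert rpde(white_noise)[0] > rpde(clean_segment)[0]

    def test_bounded_unit_interval(self, white_noise):
        assert 0.0 <= rpde(white_noise)[0] <= 1.0


class TestExtractAll:
    def test_full_battery_on_passing_phonation(self, perturbed_phonation):
        p, _ = perturbed_phonation
        fv = extract_all(p, age=65.0, gender="M")
        assert len(fv.values) == 304
        assert np.all(np.isfinite(fv.values))
        assert fv.names == feature_names()

    def test_deterministic(self, perturbed_phonation):
        p, _ = perturbed_phonation
        a = extract_all(p, age=65.0, gender="M")
        b = extract_all(p, age=65.0, gender="M")
        assert np.array_equal(a.values, b.values)

    def test_runtime_under_five_seconds(self, perturbed_phonation):
        import time
        p, _ = perturbed_phonation
        t0 = time.time()
        extract_all(p, age=65.0, gender="M")
        assert time.time() - t0 < 5.0

    def test_gain_invariant_except_declared_measures(self, perturbed_phonation):
        # amplitude-referenced measures: absolute jitter in seconds is NOT
        # gain-dependent; c0 and cycle-amplitude absolutes are
        p, _ = perturbed_phonation
        a = extract_all(p, age=65.0, gender="M")
        b = extract_all(Phonation(0.5 * p.samples, p.fs, dict(p.meta)),
                        age=65.0, gender="M")
        d = a.as_dict()
        e = b.as_dict()
        for key in ["jitter.cycle.local_mean", "shimmer.cycle.local_mean",
                    "ppe.ppe", "rpde.rpde", "dfa.alpha_norm",
                    "gne.gne_mean", "hnr.hnr_mean"]:
            assert d[key] == pytest.approx(e[key], rel=0.05, abs=0.02), key
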