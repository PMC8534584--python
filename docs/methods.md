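# Methods

`phonoscreen` re-creates, end to end, a telephone-quality sustained-vowel
analysis pipeline for Parkinson's disease (PD) screening: synthetic /a/
phonations with known perturbation ground truth, channel degradation,
quality screening, pitch tracking, a 304-measure dysphonia battery,
margin- and correlation-based feature selection with vote aggregation, and
a balanced-training / unbalanced-held-out classifier evaluation protocol.
Real clinical recordings of this kind are not publicly distributable, so
the package ships a first-class synthetic-phonation generator; every
statistical claim the test-suite makes is therefore a claim about signals
with *known* ground truth, and the limits of that substitution are stated
below.

## Synthetic phonations

A phonation is a Rosenberg-pulse glottal source train passed through a
cascade of three two-pole resonators at (710, 1100, 2540) Hz with
bandwidths (80, 90, 120) Hz — conventional values for an adult /a/ and
configuration, not physiological claims. Cycle `i` has period
`T_i = (1/f0(t_i)) * (1 + j * eps_i)` and peak gain `A_i = 1 + s * eta_i`,
with `eps, eta` i.i.d. standard normal, `j` the jitter level and `s` the
shimmer level (both dimensionless SDs of the relative perturbation);
`f0(t)` carries an optional slow sinusoidal tremor. Aspiration noise is
formant-filtered white noise mixed at a chosen RMS ratio to the voiced
signal. Synthesis runs at 44.1 kHz; the telephone channel then resamples
to 8 kHz, band-passes 300–3400 Hz (zero-phase Butterworth), quantises to
16 bits, and can add white channel noise at a chosen SNR.

One synthesis detail matters for ground truth: each cycle's pulse *starts*
with the glottal-closure fall, so the dominant excitation event sits
exactly at the cycle onset. If instead the closure falls a fixed fraction
into a cycle whose length itself is jittered, the realised excitation
periods become a moving-average smoothing of the generated `T_i`
(SD ratio ≈ 0.53 for i.i.d. jitter) and cycle-level ground truth is wrong.

What the generator does **not** emulate: vocal-tract articulation dynamics,
correlated (non-white) jitter/shimmer processes, diplophonia or
subharmonic regimes, breath groups, codec-specific (GSM/AMR) artefacts,
and room acoustics. Passing tests demonstrate correct recovery of known
perturbations through a band-limited channel — not clinical validity on
human voices.

Default class-conditional parameter distributions give the PD class
roughly doubled jitter/shimmer/noise means relative to controls (control
jitter 0.6% ± 0.2, PD 1.2% ± 0.4; shimmer 2%/4%; noise 2%/4%), ages
49.2 ± 15.9 vs 62.7 ± 12.0 years, and the cohort's published recording and
participant counts (9955/5453 control, 1987/1078 PD). The 2× separation is
a modelling choice made once for the synthetic study conditions; no
physiological fidelity is claimed.

## Quality screening and segment choice

A recording passes screening when it is ≥ 2.5 s long, ≥ 60% of its 10 ms
frames are voiced, ≤ 1% of samples sit at full scale, and a crude SNR
estimate (voiced-band energy over the > 3 kHz residual, bandwidth
normalised) is ≥ 10 dB. All four thresholds are reconstructions and
config-exposed. Feature extraction then uses the 2 s window of the 10 ms
F0 contour with the smallest F0 standard deviation, fully voiced, ties
broken earliest; the suite checks this against an exhaustive brute-force
minimiser.

## Pitch tracking

The contour estimator is a sawtooth-inspired spectral matcher: per 10 ms
frame, the square-root magnitude spectrum is interpolated onto a 0.05-ERB
grid and correlated with kernels on a 1/96-octave candidate grid. Kernels
place narrow positive cosine lobes (half the natural lobe width) at the
candidate's first and prime-numbered harmonics and half-weight negative
lobes between harmonics; rows are normalised by the positive-lobe norm, so
a perfectly matching spectrum scores 1 and a flat spectrum ≈ 0. A single
analysis window of four `f_min` periods serves all candidates.

Telephone band-limiting removes the fundamental, and for an /a/ the
formants (710, 1100, 2540) ≈ (2, 3, 7) × 363 Hz form a harmonic series of
their own — once heavy jitter destroys true harmonic coherence, a naive
spectral matcher locks onto ~363 Hz. Two safeguards address this:

1. **Envelope-autocorrelation anchor.** The Hilbert envelope strips the
   formant oscillation but keeps pulse-rate periodicity, and its
   periodicity survives cycle-timing jitter (phase noise does not
   accumulate across the envelope peaks). The anchor lag maximises a
   4-term comb score (mean of the envelope autocorrelation at lags
   τ, 2τ, 3τ, 4τ, each taken as a ±2-sample local maximum so integer lags
   see fractional-period peaks); the smallest lag within 90% of the
   maximal score wins, which rejects period doubling. Candidate search is
   then restricted to ±0.45 octave of the anchor — a sustained-vowel
   prior, appropriate because the task analyses a single steady vowel.
2. **Periodicity-supplemented voicing.** Frame strength is the maximum of
   the spectral-match score and the frame's normalised autocorrelation at
   the winning period, so severely jittered but clearly voiced frames
   survive the 0.3 voicing threshold while white noise (both scores ≈ 0)
   does not.

Per-frame F0 estimates themselves always come from the spectral matcher
(arg-max with parabolic refinement on the log-frequency grid); the
test-suite bounds them against an independent autocorrelation oracle on
clean harmonic signals, where the anchor restriction is non-decisive.

Cycle extraction seeds marks from the contour and walks the waveform
picking one dominant extremum per 0.7–1.3 period window. Peak positions
and amplitudes are refined by parabolic interpolation: at 8 kHz the raw
sample grid (125 µs) would otherwise contribute ~0.5% period noise, which
swamps jitter at the 0.5% level. The last partial cycle at the signal edge
is dropped (boundary filtering distorts it). With these choices, measured
`jitter_local` tracks ground truth within ±10% for jitter levels
0.005–0.04 after channel degradation (the suite enforces ±25%).

## The 304-measure battery

Families and counts: jitter 28, shimmer 21, HNR/NHR 4, GQ 3, GNE 6,
VFER 9, EMD-ER 6, MFCC 39, F0-vs-norms 3, wavelet 182, PPE 1, DFA 1,
RPDE 1. The classical measures in each family are fixed by their standard
definitions; the remaining slots are filled by a systematic, frozen
enumeration (the manifest in `phonoscreen/data/manifest.txt` is the
authority for names and order, and a test asserts it matches the code).

* **Jitter (28).** Fourteen statistics on each of two period sequences
  (cycle periods; 10 ms frame periods 1/F0): local mean/median, absolute
  mean/median, RAP mean/median, PPQ5 mean/median, DDP, log-period local
  mean/median, TKEO mean/SD of the normalised sequence, and the
  coefficient of variation.
* **Shimmer (21).** The cycle-amplitude block (11): local mean/median,
  dB mean/median, APQ3/5/11, DDA, log-amplitude local, TKEO mean/SD; and a
  frame-RMS-energy block (10) with the same statistics minus the
  log-amplitude slot.
* **GQ (3).** SD(T)/median, 5–95 percentile span / median, and the
  fraction of cycles deviating > 5% from the median period.
* **HNR/NHR (4).** Frame-level normalised autocorrelation around the
  expected lag (parabolic-refined between integer lags, else perfectly
  periodic input saturates near 15 dB); HNR = 10·log10(r/(1−r)),
  NHR = (1−r)/r; mean and SD of each.
* **GNE (6).** Order-13 LPC inverse filtering; Hilbert envelopes of
  1 kHz-wide bands centred every 500 Hz up to 3.5 kHz (adapted to the
  8 kHz rate); GNE = max envelope cross-correlation between bands
  ≥ 1.5 kHz apart; mean/SD of GNE, of an envelope-correlation SNR and of
  a TKEO band SNR.
* **VFER (9).** Energy, TKEO and spectral-entropy ratios between the
  bands below and above 2.5 kHz (the high band necessarily ends at the
  4 kHz Nyquist limit), as frame mean/SD plus whole-segment values.
* **EMD-ER (6).** Sifting with the 0.2 SD stopping rule; the
  dominant-energy IMF is the vocal-fold signal part and all other modes
  are the noise part; energy, TKEO and entropy ratios, raw and dB.
  Leading-IMF-count noise definitions fail on telephone-band material:
  EMD is scale-adaptive and places the first-formant oscillation itself in
  IMF 1, so "first k IMFs = noise" assigns the voiced signal to noise at
  any sampling rate.
* **MFCC (39).** 25 ms Hamming frames, 10 ms hop, 26 mel filters over
  0–4 kHz, orthonormal DCT-II, c0–c12 plus regression Δ and ΔΔ, each
  averaged over frames. Filterbank energies are floored at −60 dB of the
  frame total so phase-dependent leakage into empty bands cannot dominate
  the log scale; the floor scales with energy, preserving gain invariance
  of c1–c12.
* **F0 vs norms (3).** z-score of mean log-F0 against a per-gender
  normative table (defaults: male 120 Hz, female 200 Hz, SD 0.15 log-Hz —
  replaceable configuration), the two-sided Gaussian tail probability, and
  the ratio of observed to normative log-F0 SD.
* **Wavelet (182).** Ten-level Daubechies-8 periodised decomposition of
  the detrended voiced contour and of its logarithm; per band (10 detail +
  1 approximation): log energy, Shannon entropy of normalised squared
  coefficients, log-energy entropy, TKEO mean/SD, max |c|, IQR, and the
  band energy fraction; plus, per input, the detail-energy fraction, the
  cross-band energy entropy and the slope of log detail energy vs level.
  (2 × (11×7 + 11 + 3) = 182.)
* **PPE (1).** Semitone contour around its median, whitened by an
  order-2 least-squares predictor with intercept (which removes linear
  drift exactly — a degenerate, perfectly predictable contour returns 0 by
  a 1e-9 peak-to-peak guard), residual histogram over ±12 semitones in 60
  bins, normalised entropy.
* **DFA (1).** First-order detrended fluctuation analysis over 15
  log-spaced box sizes in [50, 1000] samples; the exponent is reported
  through the logistic map α' = 1/(1+e^−α). White noise gives α ≈ 0.5,
  integrated noise α ≈ 1.5.
* **RPDE (1).** Time-delay embedding m = 4, τ = 7 samples,
  ε = 0.12 × signal SD, first-return times up to one 50 Hz period
  (160 samples at 8 kHz), computed on every 4th anchor point for speed;
  normalised entropy of the return-time histogram.

Any family that cannot be computed raises a flag carrying the family name;
recordings are never silently imputed.

## Selection and the voting scheme

GSO performs forward selection on squared correlation with the
(orthogonalised) ±1 label vector, projecting each chosen column out of the
remainder. ReliefF uses 10 nearest hits/misses in the standardised metric
with range-normalised weight updates. Simba runs 5 passes of hypothesis-
margin gradient ascent (linear utility, learning rate 0.1 decaying as
1/√t) and ranks by w². Voting counts, per feature, its appearances in the
per-run top-30 lists across training folds; the final order is by
descending votes, then ascending mean within-run rank, then index. A
30-component PCA (fit on training data only) is provided as the feature-
transformation alternative.

## Classifiers and the two-step protocol

The SVM uses an RBF kernel with per-feature [−1, 1] scaling fit on
training data only, and a grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, …, 2³}
(the C grid's printed form in the source material is internally
inconsistent; the symmetric power-of-4 reading with 11 values is used).
Random forests explore {500, 1000} trees × {0.5, 1, 2} × √p feature
subsampling; AdaBoost explores learning rates {0.01, 0.03, 0.05, 0.1,
0.3, 0.5} with 1000 depth-2 trees. Hyper-parameter search is an
exhaustive grid with 5-fold inner CV on balanced accuracy; ties prefer
smaller C, then larger γ.

Step 1 samples a balanced subset (1500 recordings per class by default;
the sampling unit is the recording, with a participant-id column retained
so subject-wise splits can be audited), and runs stratified 10-fold CV for
a configurable number of iterations; feature ranking happens inside each
training fold, and the per-k curve (k = 1..30) uses fixed mid-grid
hyper-parameters — running the full 110-point grid inside every fold × k
cell would multiply the cost by ~500 while the curve only compares feature
counts. `chosen_k` is the smallest k within one SD of the curve maximum.
Step 2 trains on the full balanced set and evaluates exactly once on the
held-out remainder; a provenance object accumulates every id used on the
training side and refuses overlap with held-out ids.

With the study's cohort counts (1987 PD / 9955 control) and 1500 per
class, the split sizes are exactly 3000 balanced and 8942 held out (487 PD
/ 8455 control) for every seed.

## Problem sizes in the validation suite

The test-suite and `scripts/acceptance.py` use reduced but statistically
meaningful sizes chosen as desk-scale study conditions: parameter recovery
uses 20 seeds per perturbation level at 5 s duration; selection recovery
uses 20 replicate cohorts of n = 600 × 304 features with a 1 SD shift on 5
features; end-to-end sanity uses n = 800 cohorts with 10-fold × 5
iterations. Determinism is enforced by deriving every stream from one
root seed.

## Known limitations

* Pitch tracking assumes a single sustained vowel; the anchor restriction
  would be wrong for running speech (explicitly out of scope).
* At jitter ≥ ~6% the spectral matcher contributes little and estimates
  rest mostly on the envelope anchor plus time-domain periodicity.
* The per-variant enumerations inside the jitter/shimmer/wavelet families
  are principled reconstructions; their *counts* are the fixed contract.
* The EMD-ER family's dominant-mode split is a telephone-band adaptation;
  its values are not comparable to implementations that treat the leading
  IMFs as noise.
* QC thresholds, the normative F0 table, and the PD/control parameter
  separation in synthetic cohorts are configuration with documented
  defaults, not estimates from clinical data.
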