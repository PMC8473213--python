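# Methods

This note records the modelling and numerical choices behind the package:
what the synthetic generator does and does not emulate, how each feature is
defined, and where the design was genuinely open.

## Synthetic cohort model

Each subject's session follows the block design of laboratory
stress-induction protocols: five blocks of 30 s arithmetic task + 20 s rest
at 256 Hz on seven frontal electrodes (Fp1, Fp2, F7, F3, F4, Fz, F8),
250 s in total. The analysis uses the first rest window (30–50 s) and the
first 20 s of the last task block (200–220 s), giving 20 + 20 one-second
epochs per subject.

### Oscillatory structure and phase coupling

Per frequency band the channel signals share a driver phase advancing at
the band's center frequency with a small random-walk frequency wander
(step SD 0.01 rad/sample, common to all channels, hence invisible to
pairwise phase differences). Each channel adds a fixed lag and a slow
random-walk phase obtained by integrating a per-channel frequency
detuning δ(t), piecewise constant over 1 s segments and drawn i.i.d. per
segment with SD σ_f Hz.

This detuning mechanism is what makes epoch-level PLV controllable on
*band-filtered* data. Fast Gaussian phase jitter cannot do it: a narrow-band
filter removes phase fluctuations faster than the band width, so any amount
of fast jitter leaves the filtered pair locked (measured epoch PLV ≥ 0.91
regardless of the jitter SD). A within-epoch linear phase drift of d Hz,
in contrast, stays inside the band and yields epoch PLV = |sinc(d·T)|
exactly (T = 1 s). With pair detuning difference d ~ N(0, 2σ_f²), the
generator inverts E|sinc(d·T)| = target numerically (Gauss–Hermite
quadrature + Brent root finding) to choose σ_f per band and condition.

Two consequences are intentional:

- **i.i.d. segments aligned to the 1 s analysis epochs** make epochs
  exchangeable under a null configuration, so a no-effect cohort cannot be
  classified above chance through temporal autocorrelation. A slowly
  varying (Ornstein–Uhlenbeck) detuning was tried first and rejected: its
  multi-second correlation leaks "window identity" into the features and
  pushed null-cohort accuracy to ~0.75.
- **A PLV floor at low targets.** One second of a 4 Hz-wide band carries
  only ~4 independent phase samples, so the modulus statistic of even
  independent narrow-band signals sits near 0.4. Realized epoch PLV
  therefore tracks targets well above ~0.4 and compresses below it (real
  narrow-band EEG behaves the same way). Calibration of the generator is
  exact for targets ≥ 0.5 and the rank order of targets is always
  preserved.

The pair-level helper `generate_coupled_phases` additionally implements the
classic constant-lag + Gaussian-jitter model with
exp(−σ²/2) = target — exact for phases observed without band-limiting —
and is the model the calibration Monte-Carlo tests check directly.

Because all channels share one driver per band, pairwise PLV targets are a
single per-band number per condition; arbitrary per-pair target matrices
are not simultaneously realizable under a shared driver and are not
offered.

### Amplitudes, conditions and labels

Rest-condition band amplitudes (µV): delta 6, theta 4, alpha 8, sigma 2.5,
low beta 2, high beta 1.5 — an alpha/delta-dominant frontal resting
spectrum. Under stress the affected channels move in the directions the
pipeline is meant to recover: alpha ×0.70 at Fp1/Fp2/F4, high beta ×1.30
and theta ×1.25 at Fp1/Fp2/F3/F4, sigma ×1.30 at F7; PLV targets drop in
delta (0.55→0.28) and alpha (0.60→0.28) and rise in high beta (0.22→0.55).
The multipliers were calibrated once, by measuring epoch-level pooled-SD
separations on a pilot cohort, to give roughly one pooled SD per affected
feature (measured: alpha RP ≈ −1.1, high-beta RP ≈ +1.4, theta RP ≈ +1.0,
Hjorth activity ≈ −1.0, high-beta PLV ≈ +1.1; delta PLV is floor-compressed
to ≈ −0.3). Time-domain effects are emergent from the spectral changes, not
injected directly.

Background: per-channel pink (1/f) noise (SD 3 µV), raised-cosine 0.5 s
blink bumps on Fp1/Fp2 (4/min, ~50 µV), optional 50 Hz common-mode
sinusoid. Amylase values are truncated-at-zero normals (rest M 24.45,
SD 4.44; stress M 93.64, SD 13.99); the subject label applies fixed
thresholds (>60 stress, 30–60 working, <30 rest) to the post-task draw.
Assay units are treated as unit-agnostic numbers.

**What the generator does not emulate:** forward-modelled cortical sources
and realistic scalp mixing, habituation/learning across blocks, inter-subject
variability in effect direction, heart-rate artifacts, non-stationary noise.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes — not that it would reach any particular
accuracy on human recordings.

## Preprocessing

Filter → average reference → (optional ICA) → epochs.

- **FIR band-pass 1–35 Hz:** windowed-sinc (Hamming), order ⌈3.3·fs/Δf⌉
  with a 1 Hz transition, applied zero-phase by centred FFT convolution
  with odd-reflection edge padding (~53 dB stop-band, <0.1 dB pass-band
  ripple). The first/last half kernel (~1.65 s) carries the unavoidable
  edge transient; the analysis windows start 30 s into the record. The
  band-pass also removes 50/60 Hz mains, so there is no separate notch.
- **Average reference** over the seven recorded channels (the only ones
  available); applied after filtering, idempotent.
- **ICA artifact suppression (opt-in):** FastICA on the continuous record
  with the component count capped at the numerical rank (average-referenced
  data is rank-deficient), zeroing components with >60 % spectral power
  below 4 Hz (ocular proxy) or above 30 Hz (myogenic proxy);
  non-convergence falls back to the identity with a logged warning. It is
  **disabled by default** in the pipeline: on these synthetic cohorts the
  low-frequency rule cannot distinguish a genuine delta rhythm from ocular
  drift (enabling it erased the injected time-domain contrasts), and the
  simulated blinks already end up below the rejection threshold after the
  1 Hz high-pass. For real recordings with large ocular artifacts,
  `--ica` enables it.
- **Epoching:** contiguous non-overlapping 1 s epochs per condition
  window, each epoch mean-corrected over its full length per channel;
  epochs whose peak-to-peak amplitude exceeds 100 µV on any channel are
  dropped (a configurable, automated stand-in for visual inspection, whose
  amplitude criterion is otherwise unspecified).

## Features

All moments and variances use population (1/T) normalization over the 256
samples of an epoch; the Hjorth derivative is a first difference (the Δt
factor cancels in the mobility/complexity ratios). Degenerate signals
(zero variance) yield NaN cells, which the selection stage treats as
never-significant.

Multitaper PSD: NW = 4 by default (K = 7 DPSS tapers, orthonormal),
per-epoch estimation (1 Hz resolution); one-sided scaling such that
∑PSD·df equals the signal variance. Relative power integrates bands as
half-open intervals [low, high) — shared edges counted once — with the top
band including 30 Hz, and normalizes by the six-band total (1–30 Hz), not
the full Nyquist range, consistent with the 1–35 Hz filtered signal.

PLV: band filtering is applied to the continuous preprocessed record
before epoch slicing (no per-epoch filter transients; a warning fires if
epochs fall within one filter group delay of the record edges), phases come
from `scipy.signal.hilbert`, and one PLV per pair per epoch is the time
average within that epoch. Pairs are ordered lexicographically by channel
name; k channels give k(k−1)/2 pairs.

## Selection, fusion, evaluation

Screening uses the classic pooled-variance independent t-test (Welch by
flag), two-sided, α = 0.05, with optional Bonferroni correction; the
default follows the uncorrected per-test rule. Fusion concatenates the
surviving columns of the row-aligned domain tables; provenance stays in the
`time__`/`freq__`/`plv__` name prefixes.

The harness avoids test-set leakage by fitting both the z-scoring and (when
enabled) the t-test selection on training rows only, inside every CV fold
and for the held-out split — published pipelines often select on the whole
dataset first, and `paper_mode=True` reproduces that variant for
comparison. Split protocol: stratified 80/20 epoch split, 5-fold stratified
CV inside the training 80 % (mean ± SD reported), held-out 20 % scored
once. Cohorts can be aggregated per subject (default: per-subject splits,
means and SDs across subjects), pooled, or leave-one-subject-out; the
reported tables carry both CV and held-out numbers so either aggregation
can be read off. Classifier hyperparameters are fixed (no tuning): RBF-SVM
C = 1 tol 1e−3, KNN k = 5 Euclidean, Gaussian NB smoothing 1e−9, RF 100
Gini trees, CART Gini, logistic regression C = 1 tol 1e−4 (L2), LDA SVD
solver tol 1e−4. Undefined confusion ratios (zero denominator) are
reported as 0 with a logged warning. All stochastic components draw from
the run seed; identical config + seed reproduces every numeric output byte
for byte (reports avoid timestamps and use sorted-key JSON).

## Problem sizes

The test suite and the acceptance script keep simulations at sizes chosen
for tight statistical tolerances at interactive runtimes: 6-subject cohorts
for fixture-based tests, a 22-subject effect cohort (the study-scale
default) and a 6-subject null cohort in the acceptance script, 50-seed
Monte-Carlo for coupling calibration, and 200 replicates for the type-I
rate. The full suite runs in well under a minute of compute per module and
the acceptance script in about half a minute.

## Known limitations

- Epoch-level PLV targets below ~0.4 are floor-compressed (see above);
  condition contrasts placed there are attenuated, mirroring the intrinsic
  bias of short-epoch PLV rather than a defect of the estimator.
- Adjacent 1 s epochs come from contiguous signal, so they are not fully
  independent samples; the stratified epoch split mixes them, as the
  original protocol's description implies, and leave-one-subject-out mode
  is available where strict independence is wanted.
- The ICA spectral-fraction rule is a deliberately simple artifact
  heuristic; it is adequate for blink-dominated components but will remove
  genuine slow rhythms on rhythm-dominant data (hence off by default).
- EDF support is read-only (via mne); the generator exports CSV.
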