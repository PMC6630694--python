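# Methods

This note records the models behind `pcgkit`, the parameters that matter,
and the design choices made where more than one reasonable option existed.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model of the synthetic generator

A phonocardiogram is synthesized as a sum of Gaussian-windowed sinusoid
bursts on a cardiac timing grid, plus optional murmur, noise and drift:

* **S1** — 50–60 Hz (default 55), burst width ≈ 50 ms (σ = width/6),
  amplitude 1.0 ± 5 % jitter. S1 is deliberately amplitude-dominant, which
  is the physiological premise the segmenter relies on.
* **S2** — 80–90 Hz (default 85), width ≈ 40 ms, amplitude 0.55 ± 5 %.
  Placed one systole after S1; systole is 0.3 s at 60 bpm and scales with
  the cardiac period.
* **S3 / S4** (optional) — 20–30 Hz (default 25) bursts, 0.1–0.2 s after S2
  (default 0.15) and 0.07–0.1 s before the next S1 (default 0.085),
  amplitudes 0.3 / 0.25.
* **Murmur** (abnormal records only) — Gaussian noise band-passed to
  300–600 Hz and windowed over systole with a Gaussian of width systole/4,
  scaled so heart-sound power exceeds murmur power by `murmur_snr_db`
  (default 6 dB). This reproduces the defining spectral signature of
  abnormal recordings — extra power in the 300–600 Hz band where normal
  PCGs have essentially none — without claiming any specific pathology.
* **Noise / drift** — white Gaussian noise at `noise_snr_db` (default
  20 dB) relative to the heart-sound power; drift is a 0.5 Hz sinusoid plus
  a 1 Hz-low-passed random walk, amplitude 0.05 by default.

Heart rate defaults to 60 bpm with 2 % per-cycle period jitter; records are
normalized to peak 0.9 and carry ground-truth annotations for every
synthesized event. All randomness flows from one `numpy` Generator seeded
per record, so identical configurations are bit-identical. Dataset
generation derives per-record seeds from a master seed and jitters heart
rate (±15 %) and S1/S2 frequencies inside their physiological bands.

**What the generator does not emulate:** varying auscultation sites,
pediatric/adult morphology differences, friction and ambient noise bursts,
split S2, and real murmur taxonomy (systolic vs diastolic grading).
Passing tests on this phantom therefore demonstrate pipeline correctness
and the mechanics of the screening trade-off, not clinical performance.

## Sensor chain

The acquisition front end is modeled as: microphone volts (`mic_fullscale_v`,
default 0.1 V maps the dimensionless record) → pre-amplifier gain 11 v/v →
analog 20–600 Hz band-limit → DC shift to mid-supply → 10-bit ADC at 3.0 V
reference. The analog filter is a 4th-order Bessel high-pass cascaded with
a 4th-order Bessel low-pass applied causally; Bessel is used because its
near-linear phase matches what audio front ends are built for. The ADC
step is vref/2^bits = 3.0/1024 V ≈ 2.93 mV; out-of-range signals saturate
with a warning. The battery estimator is life(h) = capacity(mAh) /
load(mA) × 0.70, the usual derating rule for external losses.

## Pre-processing

Order is fixed: **spike removal → baseline correction → band-pass**.

* Band-pass: 6th-order Butterworth (3rd-order prototypes), 20–600 Hz at
  2000 Hz sampling, applied zero-phase (`sosfiltfilt`) so S1/S2 timing is
  not skewed before segmentation. Stability is verified from the biquad
  poles at design time.
* Spike removal: samples deviating > 8 MADs from the median are spike
  *candidates*, but a phonocardiogram is quiet most of the time, so genuine
  heart-sound bursts also clear any amplitude threshold. What distinguishes
  an artifact is brevity: above-threshold runs closer than 25 ms are merged
  (the crests of one oscillatory burst belong together — at 55 Hz, crests
  are ~18 ms apart) and only merged runs shorter than 10 ms — far below
  the ~50 ms S1 burst — are interpolated away. A constant record (MAD = 0)
  passes through unchanged.
* Baseline correction: zero-phase 2nd-order Butterworth high-pass at 2 Hz,
  safely below the 20 Hz band edge.

All operators are length-preserving and deterministic.

## Segmentation

The envelope is the normalized average Shannon energy
(−mean x²·ln x² per 20 ms frame, 5 ms hop, 3-point smoothed, peak-scaled).
Candidate peaks come from this envelope, but *dominance* between candidates
closer than the refractory spacing 60/HRmax (default HR bounds 40–180 bpm)
is judged on the plain 20 ms moving-average energy: the Shannon transform
deliberately de-emphasizes the largest amplitudes (−x²ln x² vanishes as
|x| → 1), so an S2 at ~0.6 relative amplitude can out-rank S1 on the
Shannon scale while the plain energy ordering is unambiguous. Peak
positions are refined to the local energy maximum within ±30 ms.

Cycles span [S1ᵢ − δ, S1ᵢ₊₁ − δ) with pre-offset δ = 50 ms so each cycle
captures the onset of its S1 and the tail of its S2; cycles outside
0.3–2.0 s are dropped with a warning, and a start clamped at 0. Indices
are 0-based, intervals half-open, times in seconds. Cycle averaging
linearly resamples to the median cycle length before the pointwise mean.

## Features

Conventions, chosen once and used everywhere:

* Standard deviation uses n−1; skewness and kurtosis divide the third and
  fourth central moments (over N) by that same s³ / s⁴, kurtosis reported
  as excess. Moments of a constant cycle are defined as 0, not NaN, so
  classifiers never see non-finite inputs.
* Percentiles use linear interpolation between order statistics.
* Shannon entropy uses a 32-bin histogram over the cycle's min–max range,
  log₂; this makes it scale-invariant and bounded by 5 bits.
* Spectral features come from the one-sided FFT power spectrum of the full
  cycle; spectral entropy is normalized by log₂(number of frequency bins)
  into [0, 1]; the peak search excludes the DC bin; the energy ratio uses
  a ±Δf window with Δf = 10 Hz by default.
* MFCC: pre-emphasis coefficient 0.95; 25 ms frames, 10 ms hop, Hamming
  window, 256-point FFT; 26 triangular mel filters over 20–600 Hz (the
  instrument's passband); log energies floored at 1e−12; orthonormal
  DCT-II; coefficients 1–13 retained (the 0th, a pure loudness term, is
  excluded — the common speech-processing convention) and averaged across
  frames. A whole-cycle single-frame mode exists as a config switch; a
  cycle shorter than one frame falls back to it automatically.

The canonical 27-name order is fixed in `features.FEATURE_NAMES`; the
reduced preset (`select.REDUCED_FEATURE_NAMES`) is kurtosis, f_max and the
13 MFCCs — 15 features.

## NCA feature weighting

Diagonal NCA with the softmax leave-one-out objective. Parameters u_k
enter the distance squared, d_ij = Σ u_k²(x_ik − x_jk)², which keeps the
effective weights w_k = u_k² non-negative without constraints; the
objective is mean leave-one-out soft accuracy minus λ·Σu_k². Penalizing
the parameters (not their squares) matters: it makes u = 0 a genuine
optimum for large λ, so irrelevant features are driven exactly to zero.
λ defaults to 1/n. Optimization is L-BFGS with the analytic gradient;
the default all-ones initialization is deterministic and makes
column-permutation equivariance exact. Inputs are expected standardized
(a warning fires otherwise); standardization parameters are always
learned on training folds only.

## Classification and costs

* Fine KNN: k = 1, Euclidean, unweighted. Weighted KNN: k = 10, Euclidean,
  inverse-squared-distance votes (1/(d²+1e−12), so an exact training-point
  match dominates). Supported metrics: euclidean, cityblock, chebyshev,
  cosine. Neighbor search is exhaustive (`brute`), which the tests verify
  against an all-pairs sort.
* Subspace ensemble: each of n_learners members trains on a seeded random
  feature subset (default dimension ⌈p/2⌉) with a linear-discriminant or
  weighted-KNN base; the ensemble posterior is the member mean. A member
  with singular within-class covariance is refit with shrinkage.
* Cost enters only at decision time: predict the label minimizing expected
  cost under the posterior. With (cost_fn, cost_fp) = (10, 1) the abnormal
  threshold on p(abnormal) is 1/11; at exact equality the abnormal label
  is chosen (the safe screening decision), which also makes the
  sensitivity-monotonicity property clean. Training is untouched, so one
  fitted model serves any cost setting.
* Cross-validation: stratified 5-fold with shuffling, standardization
  refit inside each training fold; per-fold confusion matrices are summed
  and metrics computed on the pooled matrix (also per fold). The holdout
  split is stratified at the record level (80/20 by default) so cycles of
  one recording never straddle train and test.
* Hyper-parameter search: exhaustive grid (4 metrics × k = 1..30 by
  default) minimizing cross-validated expected cost, ties broken toward
  smaller k then metric order — deliberately exhaustive rather than
  Bayesian so results are exactly reproducible.
* Record- and buffer-level decisions are majority votes over cycle
  predictions with ties to abnormal; a 10 s buffer with no detected cycles
  reports "indeterminate".

## Metrics

The eight statistics (sensitivity, specificity, FPR, precision, F-score,
accuracy, error, MCC) are computed from integer counts with the abnormal
class positive. Undefined ratios are reported as NaN with a warning —
never silently 0 — and the identities error = 1 − accuracy and
FPR = 1 − specificity hold to machine precision by construction.

## Numerical and degenerate-input choices

* WAV I/O: 16-bit PCM, scale 32768 with clipping at the positive rail;
  round-trip error is within one quantization step. Rate mismatches are
  resampled by polyphase filtering; PhysioNet's −1/1 labels map to
  normal/abnormal at read time.
* The canonical rate is 2000 Hz everywhere. (The acquisition hardware
  description also mentions a 500 Hz ADC mode; the 2000 Hz figure is the
  one used by the dataset and all processing, so it is the one the
  toolkit standardizes on.)
* Battery life: the 0.70-derating formula is implemented literally. For a
  300 mAh pack it gives ≈ 142 h at the 1.48 mA average load and 29.25 h at
  the 7.18 mA continuous-transmission load; a published figure of ≈ 41 h
  for the latter corresponds to omitting the 0.70 factor and is documented
  here rather than reproduced.
* Zero or constant signals: empty S1 lists, zero envelopes, unchanged
  spike removal, entropy 0, and an error for a zero cycle's spectrum.

## Problem sizes used by the test suite

The segmentation-recovery check uses 20 seeds × 4 heart rates
(50/60/90/120 bpm) × 8 s records at 10 dB SNR; the end-to-end screening
check uses 40 normal + 40 abnormal 10 s records (≈ 780 cycles). These
sizes give stable pass/fail behaviour on a single CPU and are the
package's declared study conditions.

## Known limitations

* The synthetic phantom is separable by design; accuracy figures on it say
  nothing about clinical data. On real corpora, expect segmentation to be
  the weakest link (no four-state HMM segmentation is included — the
  S1-dominance premise is simpler and fails on very weak or split S1s).
* NCA is validated by recovery and gradient properties, not by reproducing
  a specific learned weight vector; the 15-feature preset ships as a fixed,
  reproducible anchor independent of any NCA run.
* No ROC/AUC, no wavelet features, no deep-learning baselines, and no
  hardware acquisition paths (BLE/serial) — out of scope by design.
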