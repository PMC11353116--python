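# Methods

## Problem and scope

`mlsnet` stages mouse sleep from three simultaneously recorded signals —
one EEG channel, one nuchal EMG channel, and one eye-movement (EM) trace
from a magnetic conjunctival sensor — into the three rodent vigilance
states WAKE, NREM and REM, one label per non-overlapping 4-s epoch. The
pipeline is feature-based: ten interpretable per-epoch features feed a
small bidirectional LSTM whose per-epoch outputs pass through an MLP and
a softmax. The package also implements the surrounding machinery needed
to evaluate such a classifier honestly: signal conditioning, subject-level
leave-one-out cross-validation (LOOCV), a run-length-aware class
rebalancing augmentation, the EM-exclusion ablation, and a synthetic-data
generator so that every stage is testable without any recordings.

## Signal conditioning

Per recording, in order:

1. **Mains notch.** IIR notch at 50 Hz (quality factor 30) on every
   channel, applied forward–backward (zero phase) so epoch boundaries are
   not phase-shifted.
2. **EMG bandpass.** Order-4 Butterworth, 30–70 Hz, zero-phase. The notch
   precedes the bandpass; since 50 Hz lies inside the EMG band, the order
   matters and is fixed.
3. **Outlier clipping** on EEG and EM: samples outside the recording's
   0.01th–99.99th percentiles are set to the thresholds (motion and EMG
   contamination artifacts). Percentiles use the *inward order-statistic*
   definition (`higher` for the lower bound, `lower` for the upper): both
   thresholds are then actual data values, which makes clipping exactly
   idempotent — an interpolated percentile of a clipped signal falls just
   inside the previous threshold, so re-clipping would keep nibbling at
   the extremes. At these tail probabilities the two definitions differ
   negligibly.
4. **z-scoring** of every channel: `(x − μ)/σ` with the population σ
   (ddof = 0). Normalization is per recording, so a held-out subject
   needs no training-set statistics. A near-constant channel
   (σ ≤ 1e−12) maps to zeros instead of dividing by ~0.

Clipping is computed over the whole recording, not per epoch, preserving
cross-epoch comparability of amplitudes. No epochs are rejected: artifacts
are bounded, never discarded.

## The ten expert features

Per epoch, in fixed order: EEG band powers for delta 0.5–4 Hz, theta
6–9 Hz, alpha 8–12 Hz and upper-gamma 52–70 Hz (f1–f4); the theta/delta
ratio (f5); EMG root-mean-square (f6); EEG and EM mean absolute amplitude
(f7, f8); and the EM event frequency above the wake and REM thresholds
(f9, f10). Band power is the sum of squared DFT magnitudes over in-band
bins, averaged over the epoch's time windows; the default is a single
rectangular window spanning the 4-s epoch (configurable). A delta lower
edge of 0.45 Hz appears in parts of the literature; 0.5 Hz is the default
here and the bands are configurable `BandSpec`s. Additional bands
(upper-theta 7–8.5 Hz, broadband 0–30 Hz) are available but not part of
the canonical vector.

Decisions where the method description is silent:

* **Mean amplitude** is the mean absolute sample value — sign-free and
  well-defined on the zero-mean normalized signals.
* **EM thresholds** `A_wake` and `A_rem` are `mean + 1.96·σ` of EM samples
  within wake-labelled (resp. REM-labelled) epochs. The ±1.96σ band is
  resolved to its upper bound because events are counted as *exceedances*.
  Thresholds are fit on training subjects only (pooled), never on the
  held-out recording, to avoid label leakage.
* **EM event frequency** counts upward crossings (a sample above the
  threshold whose predecessor was at or below it) per second. Counting
  threshold-exceeding *samples* instead would scale with the sampling
  rate; event counting does not.
* The theta/delta ratio returns a capped sentinel (1e6) when delta power
  is exactly zero with nonzero theta, and 0 for 0/0.

Before classification, features are standardized column-wise (z-score)
with statistics fit on the training fold. The EM null mask used by the
EM-exclusion ablation writes 0 into f8–f10 *after* standardization, i.e.
exactly the column mean — a masked feature carries no class information.
Recordings without an EM channel get the same null value, so EEG/EMG-only
datasets are first-class inputs.

## The classifier

The primary model reads the feature sequence through a bi-LSTM with 16
units per direction (32 total), then a 32-unit ReLU MLP layer and a
3-class softmax, emitting per-epoch probabilities. Sleep states come in
bouts, so the bidirectional temporal context carries real information,
particularly for REM (short bouts, 8% of epochs).

The network is implemented directly on numpy with hand-derived gradients
(the LSTM backward pass, the strided 1-D convolutions of the variants, and
the MLP) and an Adam optimizer — the model is small enough (a few thousand
parameters) that a deep-learning framework would add nothing but weight.
Analytic gradients are verified against central finite differences in the
test suite.

Training choices the method description leaves open, fixed here and
recorded in `ModelConfig`: Adam at learning rate 1e-3, batch size 32,
cross-entropy loss, optional class weights (off by default), dropout off
by default, training sequences of 64 contiguous epochs (non-overlapping;
a trailing shorter window is kept), and "120 iterations" read as 120 full
passes over the training set. All randomness — initialization, shuffling,
dropout — derives from `ModelConfig.seed`; per-fold models are reseeded
as `seed + fold_id`, so every run is bit-reproducible.

Two variants exist for architecture ablations: `smls` replaces the expert
features with a two-layer strided 1-D CNN (kernel 7, stride 2, ReLU,
max-pool, global average pool) over the raw epoch signals and has *no*
recurrent layer (each epoch classified independently); `stmls`
concatenates the CNN embedding with the ten features and keeps the
bi-LSTM. They are supported for structural comparison, not tuned.

## Rebalancing augmentation

Training folds can be rebalanced in two steps operating on maximal
constant-label runs: runs longer than their class's mean run length are
trimmed at the tail to `ceil(mean)`; then minority-class runs are
duplicated whole — cycling in original order — until every class matches
the majority class's epoch count within ±1. Duplicating whole runs (not
single epochs) preserves the bout structure the bi-LSTM consumes. No
signal values are synthesized; a provenance map (output index → source
epoch) makes this auditable. Augmentation never touches evaluation data.
Trimmed epochs are discarded rather than re-used elsewhere.

## Evaluation

Subject-level LOOCV: each of k recordings is the test set exactly once
(training fraction (k−1)/k, = 6/7 ≈ 85.7% for the seven-mouse design).
Reported per fold: the 3×3 confusion matrix (rows true, columns
predicted, order WAKE/NREM/REM); per-class one-vs-rest precision, recall,
F1 and accuracy (the TP+TN form); overall accuracy as trace/total; macro
(unweighted) and micro averages. Zero-denominator metrics are reported as
0 and flagged. Across folds: the coefficient of variation
CV = 100·σ/μ of fold accuracies, with population σ. EM masking, when
requested, applies to training and test alike (it emulates the modality
being absent); thresholds, scaling and augmentation are fit on training
folds only.

## The synthetic-data generator

The generator emulates exactly the structure the classifier's features
measure, and nothing more:

* **Hypnogram**: a semi-Markov chain; bout lengths are geometric with
  per-state means (defaults 45 / 30 / 18 epochs for WAKE / NREM / REM —
  minutes-scale bouts, with REM bouts shortest); bout entries are drawn
  with weight occupancy/mean-length excluding self-transitions, so
  long-run occupancies track the target proportions 54.5 / 37.2 / 8.2%.
* **EEG**: unit-variance pink noise plus one state-dependent oscillation —
  delta (1–3.5 Hz) in NREM, theta (6.5–8.5 Hz) in REM, weak broadband
  theta-range activity in WAKE.
* **EMG**: white noise with state-dependent σ (3.0 WAKE; 0.9 both sleep
  states — nuchal atonia makes NREM and REM EMG near-indistinguishable,
  which is also what makes REM hard without eye movements).
* **EM**: Gaussian baseline (σ 0.6) plus stereotyped biphasic deflections
  (one 0.1-s sine cycle, amplitude 10) arriving as a Poisson process at
  0.90 / 0.05 / 0.25 Hz in WAKE / NREM / REM — the rates reported for
  freely moving mice.

Every oscillation amplitude, the noise floor, and the event amplitude are
jittered per epoch by a lognormal factor (σ_log = 0.8), and per-subject
lognormal gains (σ_log = 0.1) vary the state-level emphases across
animals. The jitter values are calibration constants chosen once so that
the three states' feature distributions overlap realistically: the
classifier should neither saturate at 100% nor fall below 90% overall
accuracy under the default conditions, and the REM/NREM discrimination
should ride substantially on the EM channel (as it does in real mice), so
that null-masking the EM features costs several accuracy points.

What the generator does **not** model: spindles, K-complexes, circadian
structure, transition epochs, recording drift, electrode artifacts beyond
heavy tails, or empirical bout-length distributions (geometric is
memoryless). Passing end-to-end tests on this data therefore shows the
pipeline recovers state structure of the kind the features encode; it
does not certify performance on any real recording.

## Problem sizes and determinism

The default synthetic study is 7 subjects × 1 h at 500 Hz (6,300 epochs
total) with 120 training passes per fold — large enough that fold
accuracies stabilize to a few tenths of a point, small enough for a
desk-scale run. `scripts/acceptance.py` runs exactly this study twice
(with and without the EM mask) plus the dataset arithmetic, from a single
command-line seed; every random stream in the package descends from
explicit seeds, and repeated runs are bit-identical.

## Known limitations

* The EM event-frequency estimator counts threshold crossings without
  hysteresis; heavy baseline noise near the threshold can double-count an
  event (the generator's event waveform is steep enough that this is a
  ~10% effect at realistic settings).
* The numpy training loop is single-threaded BLAS-bound; it is sized for
  thousands, not millions, of epochs.
* EDF support covers reading (via MNE); writing is columnar text only.
* The three-state alphabet is fixed; human five-stage scoring is out of
  scope.
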