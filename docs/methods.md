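# Methods

This note documents the models, procedures and numerical choices behind
`csspm`: what is computed, under which assumptions, and which decisions were
genuinely open.

## Problem setting

Patient-specific seizure prediction is cast as binary classification of 30-s
multichannel EEG segments: preictal (the 30 min before a seizure onset,
class 1) versus interictal (more than a guard margin away from any seizure,
class 0, margin 4 h by default). Ictal and postictal time, guard margins and
the preictal windows of non-evaluable seizures are excluded from the task.
A seizure whose onset falls less than 30 min after the previous seizure's
end is not evaluable: it has no clean preictal window and is dropped from
both training and scoring. Subjects qualify with at least four evaluable
seizures and fewer than ten seizures per day of recording (the daily rate is
computed as total count over record duration; the convention for calendar
days was not fixed by the setting and this is the simplest consistent
choice).

## Preprocessing

Segments are transformed per channel to a magnitude STFT image. The
transform uses a Hann window (default 256 samples = 1 s at 256 Hz) with 50%
overlap, magnitudes without log scaling, and only frames that lie fully
inside the segment, so every sample of a subject has identical shape. The
window length, overlap and scaling are configurable because the upstream
convention is not uniquely determined; the defaults here follow the common
CNN-on-STFT seizure-prediction setup. The DC bin and all bins whose center
frequency falls in the power-line bands 57–63 Hz and 117–123 Hz are
*removed* (not zeroed), so downstream shapes encode the exclusion.

Class imbalance is handled by oversampling the preictal class of the
*training* set only: the 30-s window slides at a per-subject stride S chosen
by exact inversion of the window-count formula
`count = floor((len − 30)/S) + 1` so that the preictal count matches the
interictal count as closely as possible without exceeding it by more than
one window; S is clamped to (0, 30] s, i.e. the preictal class is never
downsampled. Test and validation data always use the non-overlapping 30-s
stride so their sample counts reflect real time.

All interval arithmetic uses half-open `[start, end)` intervals in seconds,
which makes window counting and boundary tests exact.

## Classifier

The network maps a `(channels, freq, time)` spectrogram to a 2-class softmax.
Three blocks of batch-normalization → convolution (ReLU) → max-pooling are
followed by FC(256, sigmoid) and FC(2, softmax). Block 1 is specified as a 3D
convolution with `16n × 5 × 5` kernels, stride `1 × 2 × 2`, where `n` is the
channel count: because the kernel spans the entire channel axis at stride 1,
that axis collapses to length 1 and the operation is mathematically a 2D
convolution with `n` input channels and `16n` feature maps; it is implemented
as such and the "reshape to 2D" step becomes the identity. Blocks 2–3 use 32
and 64 3×3 kernels at stride 1 with 2×2 pooling.

Open details resolved here (all configurable):

- **Padding.** Unstated upstream; default `"same"` zero padding, which lets
  reduced desk-scale spectrograms survive three pooling stages. `"valid"` is
  available.
- **Dropout placement.** "Dropout 0.5 on both fully connected layers" is
  read as inverted dropout on the *input* of each FC layer; dropout after
  the softmax would leave the probability simplex.
- **Initialization.** Glorot-uniform from a recorded seed.
- **Batch normalization.** Per-feature statistics over batch and spatial
  axes, biased variance, running-statistics momentum 0.99 (the common
  framework default), frozen in evaluation mode. With few optimization
  steps the running statistics lag the batch statistics, so evaluation-mode
  accuracy is only meaningful after a few hundred steps — one reason the
  benchmark uses 20 epochs rather than fewer.
- **No per-sample standardization**: the leading batch-normalization layer
  absorbs input scale.

The network, its gradients and the Adam optimizer are implemented directly
in numpy (im2col convolutions); backpropagation is verified against central
finite differences in the test suite.

## Training algorithm

Per epoch, every training sample — labeled or not — is seen exactly once in
shuffled minibatches. Each sample gets Gaussian input augmentation
`x′ = x + ε`, `ε ~ N(0, (σ·s)²)` with σ = 0.15 and `s` the per-subject
median absolute spectrogram amplitude (σ is specified relative to a robust
data scale so it is meaningful across subjects; unstandardized magnitudes
have no natural unit), and a dropout-active forward pass. The loss is

    L = L_c + ω(t) · L_con

- `L_c`: cross-entropy over labeled batch members, normalized by the number
  of labeled members `|B ∩ L|` (keeps the supervised gradient scale
  independent of the labeled fraction; normalization by `|B|` is available
  behind `supervised_norm="batch"`). Probabilities are clipped to
  `[1e−7, 1 − 1e−7]` before logs. A printed form of this loss with a doubled
  sign would be negative; the standard nonnegative cross-entropy is used.
- `L_con = (1/(C|B|)) Σ ‖z_i − Z̃_i‖²` over all batch members, with targets
  from the temporal ensemble.
- `ω(t) = ω_max exp(−5(1 − t/τ)²)` for `t ≤ τ`, else `ω_max`
  (ω_max = 30, τ = 30); continuous at τ and nondecreasing.

After each epoch the ensemble updates `Z ← αZ + (1−α)z` (α = 0.6) using each
sample's training-mode prediction recorded when it was last seen that epoch
(one stochastic forward pass per sample per epoch — the temporal-ensembling
formulation), and targets are bias-corrected by `1/(1 − α^t)` with `t` the
1-based count of completed epochs, so the t = 1 target equals the first
prediction exactly.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) with learning rate λ_max =
5·10⁻⁴, flat until the final `rampdown_length` epochs (default 30 of 50) and
then decayed by `exp(−12.5 u²)` with `u` rising linearly from 0 to 1 — a
time-reversed Gaussian ramp whose exact parametrization was open; the form
here is monotone, continuous at the ramp start and ends at `λ_max e^−12.5`,
and is configurable. The checkpoint with the highest *segment-level*
validation accuracy is returned (accuracy is computed in evaluation mode
without augmentation; alarm-level validation was the alternative reading and
is not used). Ties keep the earliest epoch, for determinism.

All random streams — initialization, epoch shuffling, augmentation noise,
dropout — are derived from `(seed, epoch, batch)` keys. Consequently the
semisupervised trainer with ω_max = 0 and no unlabeled data consumes exactly
the same randomness as the plain supervised baseline and reproduces its
trajectory bit-for-bit; this equivalence, and the ensemble target's equality
with the explicit geometric weighted sum, are asserted in the tests.
Minibatches are drawn uniformly without stratifying by labeled status; an
all-unlabeled batch contributes a consistency gradient only.

## Cross-validation partitioning

A subject with N evaluable seizures yields N "seizure recordings": the
interictal samples, in chronological order, are split into N contiguous
parts with sizes differing by at most one (remainder to the earliest parts),
and part j is paired with seizure j chronologically (the pairing order was
open; chronological is deterministic and keeps each recording a contiguous
time span). Contiguity, rather than random assignment, prevents temporal
leakage between folds. Each recording serves once as the test set;
validation and the labeled recordings are drawn uniformly at random from the
rest (seeded), the remainder is used unlabeled, and N − 2 − n_labeled > 0 is
enforced. Preictal oversampling is applied after role assignment, to
training-role recordings only.

## Alarms and scoring

Per-segment decisions become alarms by the k-of-n rule: an alarm fires at
the first segment whose trailing window of n = 10 decisions contains at
least k = 8 preictal calls, provided 30 min have elapsed since the previous
alarm; the first n − 1 segments cannot trigger. An alarm at time `a`
predicts an onset inside `[a + SPH, a + SPH + SOP]` (SPH = 5 min,
SOP = 30 min, both ends closed — closed intervals make boundary cases
deterministic). Alarm–seizure pairing is greedy earliest-to-earliest with
each alarm crediting at most one seizure; unmatched alarms are false alarms
and unmatched seizures are misses, so TP + FN always equals the evaluable
seizure count. FPR divides false alarms by the test recording's interictal
hours. Significance against a chance predictor uses the per-seizure hit
probability `prob = 1 − e^(−FPR·SOP)` and the binomial upper tail
`p = Σ_{i≥k} C(K,i) probⁱ (1−prob)^(K−i)`; k = 0 gives p = 1 by convention.
Aggregation over repeated runs and folds computes per-fold means and sample
standard deviations across runs first, then unweighted means across folds; a
single run per fold reports a standard deviation of 0 with a warning.

## Synthetic EEG generator

Each channel is independent Gaussian noise shaped to a `1/f^β` power
spectrum (β = 1 by default), scaled to a fixed RMS — the simplest stationary
background with an EEG-like spectrum. In each 30-min pre-onset window an
*independent* band-limited noise component (brick-wall FFT bandpass of white
noise) is added with variance `(g − 1)·P_band`, where `P_band` is the
channel's background power in the configured band; since independent
components add in power, the preictal/interictal band-power ratio equals the
gain `g` exactly in expectation, which makes the effect size auditable with
a Welch periodogram. The boundary is hard (no ramp) so label edges are
exactly testable, and `g = 1` makes preictal and interictal
indistinguishable by construction. Seizures carry a high-amplitude 3 Hz
sinusoid and are never used for training.

What this generator deliberately does **not** model: artifacts (blinks,
EMG, electrode pops), nonstationary background drift, channel correlation,
or any physiologically realistic preictal dynamics. Passing the benchmark
therefore shows that the training algorithm extracts a band-limited
spectral signature from mostly unlabeled data under controlled conditions —
not that it would reach any particular performance on clinical EEG.

## Benchmark study conditions

The packaged benchmark uses one synthetic subject per seed: 4 channels at
64 Hz, an 8-h record with five seizures (30 s each, 90 min apart), theta
band (4–8 Hz) power gain 2.0, interictal guard margin reduced to 30 min so
the short record contains interictal data. Spectrograms are reduced to
32 × 30 (1-s Hann window, no overlap). Folds use one labeled training
recording; training-role interictal data is strided at 45 s with preictal
overlap-balancing, test/validation at the non-overlapping 30 s. Training
runs 20 epochs with ramp τ = 14 and a 8-epoch learning-rate ramp-down
(ramp *shapes* and all other hyperparameters at their defaults; the epoch
count is scaled with the problem size, and with it the ramp lengths,
because the full 50-epoch schedule is tuned to datasets orders of magnitude
larger). Five seeds are run; the leave-one-out fold index rotates with the
seed so all five folds are exercised. Four arms share every seed and fold
manifest: the consistency-trained model, the supervised baseline on the
labeled recording only, the ablation without unlabeled data, and the
ablation with σ = 0.

## Known limitations

- The numpy network is CPU-bound and sized for desk-scale inputs; full
  256-Hz, 23-channel spectrograms train slowly.
- The k-of-n alarm window runs over the decision sequence and does not reset
  across gaps between non-contiguous test intervals.
- `compute_balance_stride` assumes equal-length preictal intervals (true
  under the fixed 30-min label window; clipped first-preictal windows make
  the count approximate).
- EDF input requires the optional `mne` dependency; seizure annotations must
  be supplied by the caller since annotation formats are corpus-specific.
  Records and sample stores are exchanged as documented HDF5 containers.
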