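# Methods

## Problem setting

Myoelectric prosthesis control requires classifying short windows of
surface-EMG (sEMG) into intended movements with minimal latency and
hardware.  This package implements a two-channel pipeline built around
unsupervised feature learning: continuous recordings are cut into 250-ms
windows advanced every 125 ms (50% overlap), a convolutional sparse
autoencoder (CSAE) learns a compressed temporal representation of the raw
standardized signal without labels, and a light attention-pooled classifier
maps those frozen features to gestures.  Two transfer protocols sit on top:
few-shot calibration of the decision layers to an unseen user, and
incremental expansion of the gesture vocabulary by widening the softmax
layer with weight transfer.

## Data model and evaluation protocol

A cohort is a set of `Recording`s, one per (subject, gesture, trial):
an L x C matrix at sampling rate `fs` (the reference protocol: C = 2
channels over the flexor and extensor muscles, 4 kHz, six 5-s trials per
gesture, eight subjects).  Windows inherit (subject, gesture, trial)
provenance, which drives a strict leave-one-subject-out (LOSO) scheme:

* **Source domain** (the seven remaining subjects): trials 1-4 train,
  trial 5 validates, trial 6 is the held-out test ("pooled" protocol).
* **Target domain** (the held-out subject): trial 1 calibrates, trial 2
  validates, trials 3-6 are the final test ("adapt" protocol).

Standardization is per channel, with mean and standard deviation pooled
over all training windows of the fold and reused for validation, test and
the target-subject and expanded datasets.  Per-channel (rather than global)
statistics were chosen because the channels are distinct sensors on
distinct muscles.  A zero-variance channel is floored at std = 1e-8 with a
warning.  A leakage guard asserts on every fold that no (subject, trial)
pair used for scaler fitting or training appears in any evaluation
partition.

Windowing drops any incomplete tail (fixed-shape model input), giving
floor((L - T)/S) + 1 windows; indices are 0-based, windows half-open,
trial ids 1-based.

## The autoencoder

The encoder applies two strided 1-D convolution blocks (stride > 1,
learnable downsampling in place of pooling) and a stride-1 bottleneck
convolution; every layer uses LeakyReLU (slope alpha = 0.01 by default,
chosen as a conventional "small positive" value).  "Same"-style padding
keeps the temporal sizes exactly divisible by the strides, so the mirrored
decoder — transposed convolutions with the same stride values in reverse
order, then a linear stride-1 output convolution — restores the input shape
T x C; indivisible shapes are rejected at build time.  Weights are
He-Normal initialized under the config seed.

The training loss is the elementwise-mean squared reconstruction error plus
an L1 activity penalty on the bottleneck output Z:

    L = mean((X - X_hat)^2) + lambda * sum|Z| / N.

Two conventions are fixed deliberately: the penalty applies
*post-activation* (it penalizes the representation the encoder actually
emits), and the absolute sum is averaged over the batch so that lambda's
meaning does not depend on batch size.  The loss decomposes exactly into
the lambda = 0 loss plus the penalty, which the tests assert.

Optimization is AdamW (decoupled weight decay 1e-4, skipped for 1-D
parameters) with a plateau scheduler (factor 0.5, patience 5, floor 1e-5),
early stopping (patience 10 by default) and restoration of the
best-validation parameters.  The same machinery drives every supervised
stage.  All layer sizes are configuration; two reference configurations are
provided:

| | filters | kernels | strides | D | T -> T' |
|---|---|---|---|---|---|
| default | 32, 64 | 7, 5, 3 | 4, 5 | 32 | 1000 -> 50 |
| desk scale (`small_csae_config`) | 16, 32 | 7, 5, 3 | 5, 2 | 16 | 250 -> 25 |

The desk-scale strides were chosen to keep T' large enough (25 steps) for
the head to average amplitude information over time; with very short latent
sequences the per-window estimate of each channel's activation level is too
noisy.  `l1_coeff` defaults to 1e-7, the regime where a minimal penalty
helps without starving the representation (see the sweep below).

## The classifier

The trained encoder is copied, frozen (enforced bitwise by hashing each
parameter group before and after every training entry point), and topped
with: layer normalization over the feature axis per timestep (suppressing
inter-trial/inter-subject scale variance), one stride-1 temporal
convolution with LeakyReLU, additive self-attention pooling
(e_t = v · tanh(W h_t + b), weights softmax(e), context = sum a_t h_t — the
simplest scoring mechanism consistent with per-timestep importance
weighting), a two-stage MLP and a softmax output over an explicit ordered
class list.  Argmax ties break to the lowest class index.  Training
minimizes categorical cross-entropy (probabilities clamped at 1e-12) on
head parameters only; since the encoder never moves, latent features are
precomputed once per dataset, which makes head training cheap.

Dropout is off by default; the desk-scale head enables 0.4 on the MLP
stages because with few independent trials per gesture the head otherwise
overfits trial-specific carrier realizations.

## Transfer protocols

**Few-shot calibration.**  "Final fully-connected layers" is interpreted as
both MLP stages plus the output layer (the decision-making layers, plural);
encoder, layer norm, head convolution and attention stay frozen.  The
calibration set is the target subject's trial 1, validation trial 2, per
the split plan.

**Class expansion.**  The 6-unit output layer is replaced by a K'-unit one;
weights and biases of each original class are copied into its new unit, so
original-class pre-softmax logits are preserved *exactly* (the features
below are frozen and shared).  New units are freshly He-Normal initialized
under a seed.  Phase I trains only the new output layer — and since
everything below it is frozen, its input features are precomputed once and
the phase reduces to softmax-regression-style updates (exact, and an order
of magnitude faster than backpropagating through the head).  After
reloading the best Phase-I checkpoint, Phase II unfreezes the head
convolution, attention and MLP (layer normalization stays frozen with the
encoder) at a significantly lower learning rate — 0.1x by default, 0.25x
in the desk-scale protocol.  Dropout is suspended during Phase II: the
phase refines an already-converged solution, and stochastic masking only
perturbs it away from that optimum.  A Phase-II rate >= Phase I's warns
but proceeds.  `forgetting_report` compares original-class F1 before and after
expansion, both over the full 10-way output and restricted to the original
six logits.

## Metrics

Per-class precision, recall and F1 are computed one-vs-rest from the
confusion matrix; zero-division cases yield 0 and are flagged.  The micro
average pools TP/FP/FN and therefore equals accuracy for single-label
multi-class prediction (asserted as an identity test).  Cross-validated
results are mean ± standard error of the mean, SE = sd(folds)/sqrt(n).
`confusion_flow(report, a, b)` reports the fraction of class-a errors
predicted as b and is NaN (reported as undefined) when a has no errors.

## Synthetic cohorts

Real sEMG during isometric contraction is close to amplitude-modulated
band-limited noise, and that is exactly what the generator produces:

    x_c(t) = gain_{s,c} * j_trial * env_{g,c}(warp_s(t)) * carrier(t)
             + noise_floor * w(t)

with a zero-phase band-pass-filtered Gaussian carrier (fresh per trial,
unit variance), piecewise-linear gesture envelopes in [0, 1], per-subject
log-normal channel gains plus a smooth sinusoidal time-warp (emulating
electrode placement and physiology differences), log-normal trial gain
jitter (sigma 0.05), and white sensor noise.  Generation is bit-reproducible
and order-independent (every recording has its own seed substream).

Gestures are encoded in two ways at once: a per-gesture channel-balance
angle (equally spaced over the flexor-extensor plane) and a per-gesture
burst (amplitude-modulation) rate of 4-14 Hz.  Base amplitudes stay below
0.5 so that the combined gestures of the 10-class preset — clipped sums of
the thumb envelope and a finger envelope — remain within [0, 1] and carry a
distinct overall magnitude; the combined classes still land between their
constituents in angle, which reproduces the hierarchical base-vs-combined
ambiguity (e.g. ring vs thumb-ring) that drives the forgetting analysis.

Presets (full scale: 4 kHz, 5-s trials, carrier 20-450 Hz; reduced:
1 kHz, 1.5-s trials, carrier 20-110 Hz so the oversampling ratio — and
hence compressibility — matches the full-scale setting):

* `easy6` — 8 subjects x 6 gestures x 6 trials, mild subject shift (0.05),
  noise floor 0.01: the within-cohort classification regime.
* `shifted6` — subject shift 1.0: strong cross-subject degradation, the
  regime for few-shot adaptation.
* `easy10` — the 6 base gestures plus 4 thumb-finger combinations.
* `temporal2` — two classes with identical per-channel amplitude
  distributions, differing only in which channel's burst train leads by a
  quarter period; any method blind to temporal structure is at chance here.

What the generator does *not* emulate: motor-unit action potentials,
electrode shift, fatigue, non-stationary noise, or realistic inter-gesture
correlation structure.  Passing tests on these cohorts therefore
demonstrates that the pipeline's mechanisms work (feature learning,
transfer, expansion, temporal sensitivity) — not that the specific scores
transfer to real recordings.

## Desk-scale reference experiments

`semglearn.experiments` fixes the problem sizes used by the test suite and
the reproduction script: reduced presets, the compact model configurations,
30-epoch autoencoder training (patience 8, rate 2e-3), 200-epoch head
training (patience 30, rate 2e-3), Phase II at 5e-4 with a 300-epoch
budget, and one LOSO fold per run with the fold index rotating with the
seed.  The sparsity sweep uses a 4-subject cohort (lambda grid 0, 1e-7,
1e-4, 1e-1) because the penalty mechanism does not need the full cohort.
These sizes were chosen so that the complete study runs on one CPU in
about a quarter of an hour while leaving comfortable margins on its
qualitative outcomes.

## Numerical choices and edge cases

* All computation is float64 numpy; gradients of every operator are
  verified against central finite differences (1e-4 relative).
* Early stopping compares validation loss with a 1e-12 tolerance; the best
  state is deep-copied, so "restore" is bitwise.  The starting parameters
  take part in best-validation selection: a stage that never improves
  validation ends exactly where it began (this is what makes Phase II
  monotone with respect to Phase I in validation terms).
* Cross-entropy clamps probabilities at 1e-12; scaler std at 1e-8;
  argmax ties break low; one-hot encoding follows the explicit class list.
* The cost reporter counts multiply-accumulates analytically from layer
  shapes (1 MAC = 2 FLOPs, 4 bytes per parameter/activation) and is
  invariant to parameter values.
* Checkpoints are self-describing HDF5 (schema version, config JSON,
  parameters, scaler, class list).

## Known limitations

* The neural-network core is a compact numpy implementation (reverse-mode
  autodiff, 1-D conv/transposed-conv/dense/layer-norm/LSTM, AdamW); it is
  single-threaded and dense, adequate for the desk-scale models but not for
  large-scale training.
* The FCAE baseline pairs its bottleneck with a random forest, and the
  classical baseline uses a fixed six-feature set (MAV, variance, zero
  crossings, waveform length, slope-sign changes, RMS; zero-crossing
  threshold 0 on standardized signals) — reasonable, documented choices
  where several variants exist.
* `temporal2`'s contrast depends on the dense autoencoder failing to
  preserve usable temporal structure at its bottleneck; a much larger FCAE
  could narrow the gap.
* Reading the original recordings' native MATLAB container is out of
  scope; cohorts are exchanged as per-trial CSVs plus a manifest, or HDF5.
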