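# Methods

## Data model and preprocessing

A recording is a set of per-sensor streams on a shared integer sample
grid (~10 Hz; 50 samples ≈ 5 s — the rate is metadata only, all indexing
is in samples). Each timestamp carries nine channels per sensor in the
fixed order (ax, ay, az, wx, wy, wz, angx, angy, angz). Synchronization
restricts all streams to the intersection of their timestamp grids and
requires per-timestamp labels to agree across sensors.

Windowing is half-open and 0-based: window *n* of a contiguous
single-label segment covers `[n·step, n·step + T)`; a segment of length
`N_seg` yields `⌊(N_seg − T)/step⌋ + 1` windows. Windows are emitted only
where the label is constant over all T samples and the timestamp grid has
no jump — label transitions and recording gaps silently end a segment
rather than producing mixed-label windows.

The preprocessing order is: encode → wavelet smooth → normalize.
Normalization is a per-(sensor, channel) z-score whose statistics are
fitted on the training portion only and reused verbatim on held-out data;
channels with (near-)zero variance map to 0 rather than dividing by a
tiny number.

## Wavelet smoothing

Each window channel passes through a one-level discrete wavelet
decomposition; only the approximation (low-pass) coefficients are kept.
Defaults: Daubechies-4 (8 taps), level 1, symmetric boundary extension,
chosen as the minimal configuration whose output length reproduces the
architecture's published 28-sample feature map from a 50-sample window
(`⌊(50 + 8 − 1)/2⌋ = 28`). Keeping coefficients (rather than
reconstructing a same-length smoothed signal) is deliberate: the
decimated length is what the downstream network expects. The
`periodization` mode is available when a non-redundant orthonormal
transform is wanted (exact energy conservation; used by the energy
tests); the symmetric default is slightly redundant at the boundaries
and therefore not exactly Parseval.

## Network

Geometry for the defaults (28 × 2 sensors × 9 channels, 7 classes):

| stage | maps | size | params/instance |
|---|---|---|---|
| per-channel LSTM (univariate input) | 32 | 28 | 4352 |
| per-channel 1-D conv, kernel 5, same | 8 | 28 | 1288 |
| batch norm | 8 | 28 | 32 |
| max-pool(2) | 8 | 14 | 0 |
| channel concat + reshape | 1 | 14 × 72 | 0 |
| per-sensor 2-D conv 3×3, same | 8 | 14 × 72 | 80 |
| batch norm / max-pool 2×2 | 8 | 7 × 36 | 32 / 0 |
| sensor concat | 16 | 7 × 36 | 0 |
| fused 2-D conv 3×3, same | 32 | 7 × 36 | 4640 |
| batch norm / max-pool 2×2 (ceil) | 32 | 4 × 18 | 128 / 0 |
| flatten → dense 64/32/16/(dropout)/8/7 | — | 2304 → 7 | 147520/2080/528/136/63 |

Choices that the published construction tables force or leave open:

- **Univariate LSTM input** (in_dim = 1): forced by
  4352 = 4·(32·(1+32)+32).
- **Conv kernels**: 1-D kernel 5 (1288 = 8·(5·32+1)); both 2-D kernels
  3×3 (80 = 8·(9·1+1), 4640 = 32·(9·16+1)); all convolutions use same
  padding so only pooling changes extents.
- **Pooling modes**: the first pools use floor (28→14, 14×72→7×36); the
  final 2×2 pool uses ceil (7→4). Floor-mode stages validate divisibility
  at spec construction and name the offending stage.
- **Activation and placement**: ReLU for conv and dense hidden layers;
  batch normalization sits after the activation. Batch-norm parameters
  are counted as 4 per map (scale, shift, and the two running statistics)
  to match the construction tables' bookkeeping.
- **Dropout rate** 0.5 at the 16-unit layer (the tables list the layer
  without a rate).
- **Initialization**: Glorot-uniform kernels, orthogonal LSTM recurrent
  blocks, zero biases except the forget gate at 1; all drawn from one
  seeded generator, so a (spec, seed) pair fully determines the model.

The whole network — grouped LSTM, grouped 1-D convolution, 2-D
convolution, batch norm, max-pooling, dense, dropout, softmax, Adam, and
the full backward pass — is implemented in NumPy (`hear.nn`). Gradient
correctness is established against central finite differences in float64
at ~1e-7 relative error (tests nudge all parameters off zero first so no
ReLU sits exactly on its kink, where the subgradient convention and a
two-sided difference legitimately disagree). Parameter counts have two
independent routes — closed-form rules on the spec and enumeration of the
built model's arrays — that tests require to agree.

Batch-norm running statistics use momentum 0.9 and eps 1e-3; inference
mode uses running statistics and disables dropout, so inference is
deterministic.

## Losses

Cross-entropy `−log p_t` and focal loss `−α (1−p_t)^γ log p_t` over
softmax probabilities, batch-averaged; probabilities are clipped at
1e-7 before the logarithm. As printed in the source formula the focal
loss lacks the leading minus sign (it would be negative and unbounded
below); the implementation restores it, matching the loss construction
the method builds on. α and γ accept scalars (applied to the true class
uniformly; α = 0.25, γ = 2 defaults) or per-class vectors. The logit
gradient is computed analytically with the softmax folded in; γ = 0,
α = 1 reduces to cross-entropy exactly, gradient included.

## Synthetic data generator

The study's recordings of ten elderly volunteers are private, so
experiments run on a generator that reproduces the statistical features
the method exploits rather than biomechanics:

- per-channel quasi-periodic signal: class base frequency (1.2–5 cycles
  per window, well inside the wavelet pass-band) times a per-channel
  multiplier, plus a weaker first harmonic;
- cross-sensor correlation: both sensors see the same clean signal
  scaled by per-sensor gains (second wrist at 0.5–0.9);
- inter-class similarity: classes are separated by ≥ 0.8 cycles/window
  except two deliberate pairs (cooking/keyboarding and washing-face/
  washing-dishes) at gap 0.25 with shared amplitudes, phases and gains —
  these supply the hard samples a focusing loss is meant to rescue;
- noise: per-window Gaussian phase jitter (σ = 0.8 rad) and per-sample
  Gaussian noise (σ = 1.0).

The noise defaults were fixed once against the suite's calibration
property — a nearest-centroid classifier on raw balanced windows must
reach at least 60% without saturating (it reaches ≈ 0.82) — and were not
revisited afterwards. Scenario S1 gives every class 708 windows; S2–S5
starve two designated classes to 200. Reduced-scale runs keep the
708 : 200 ratio (e.g. 150 : 42).

What the generator does **not** emulate: non-stationarity within an
activity, inter-subject variability, sensor drift and calibration error,
heterogeneous sampling rates, label noise at activity transitions.
Passing tests therefore show that the implementation realizes the method
and that the loss-function effect appears under controlled conditions —
not that the published accuracy figures transfer to real recordings.

## Training and evaluation

"Hold-out cross-validation" is read as a single stratified hold-out
split (train fraction 0.8, floor on the train side), repeated over seeds
for error bars. "Train until the loss converges" is made operational as
early stopping on validation loss with patience 10 (default) and a
200-epoch cap; the best-validation weights are restored. A NaN loss
aborts with a diagnostic rather than continuing.

Metrics come from the confusion matrix: per-class precision, recall, F1,
overall accuracy, and **macro** (unweighted) averages — the published
tables do not name their averaging, so macro is assumed and labeled in
all outputs. A class absent from an evaluation set gets recall 0 and a
warning flag. scikit-learn's metric implementations are used only as an
independent oracle in tests, never in the reporting path.

The comparison harness fans one base seed out with fixed offsets to data
generation, splitting, weight initialization and batch shuffling, so the
two losses in a pair (and every γ in a sweep) see byte-identical
conditions; with identical losses in both slots the paired results
coincide exactly, which the suite asserts.

## Problem sizes in the shipped tests

The acceptance-style training checks run at reduced scale: the S2-style
focal-vs-cross-entropy comparison uses majority 100 / minority 28 windows
per class over 5 seeds, and the balanced learnability run uses 150
windows per class, both with the full default architecture and the
study's optimizer settings (Adam, 2e-4) under a 60-epoch cap with
patience 10. At this scale the batch size is reduced to 32 — the default
128 on a few hundred training windows yields so few optimizer steps per
epoch that neither loss approaches its convergence regime in reasonable
time; both losses in a comparison always share the batch size, so the
contrast is untouched. These sizes are the package's choice of a
desk-scale version of the full 708-window design; the imbalance ratio
and every architectural setting are unchanged.

## Known limitations

- Training is CPU NumPy; wall-clock cost is roughly 0.3–0.5 s per
  batch-128 step at the default architecture. Full-scale (708 windows per
  class) runs are feasible but take tens of minutes per model.
- The LSTM processes channels independently (univariate inputs) by
  design; cross-channel structure enters only through the fusion stages.
- Only 2×2 spatial pooling is implemented for the 2-D stages, matching
  the architecture; other pool shapes raise.
- The generator's similarity structure is frequency-based; methods that
  exploit amplitude-only differences would see an easier problem than
  real data poses.
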