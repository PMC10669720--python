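# Methods

This note documents the modeling and numerical choices behind
`pcgcaps`: what the pipeline computes, which parameters matter, what
the synthetic data does and does not emulate, and where the design was
genuinely open.

## Preprocessing

A recording (mono or stereo WAV; stereo is averaged to mono, since the
network input is single-channel) passes through four steps in a fixed
order:

1. **Segmentation.** Non-overlapping clips of `duration_s` (default
   5 s); the trailing remainder is discarded, and a recording shorter
   than one clip yields nothing. 5 s at 44.1 kHz is 220,500 samples.
2. **Downsampling** to 2 kHz by polyphase FIR resampling
   (`scipy.signal.resample_poly`), whose anti-aliasing low-pass keeps
   the sub-1 kHz band — all of S1/S2 (< 200 Hz) and murmur energy
   (~150–700 Hz) — intact.
3. **Peak normalization** per clip to max |x| = 1. Applied after
   slicing so each clip is scaled independently; an all-zero clip is
   passed through with a warning rather than dividing by zero.
4. **MFCC extraction** to a 128 × 16 matrix.

### MFCC convention

Only the 128 × 16 input shape is externally constrained; the framing is
this package's convention, chosen so a 10,000-sample clip tiles into
exactly 16 full frames with no padding or truncation:

| parameter | value | rationale |
|---|---|---|
| frame length | 1000 samples (0.5 s) | 16 = ⌊(10000 − 1000)/600⌋ + 1 exactly |
| hop | 600 samples (0.3 s) | ditto |
| FFT size | 1024 | next power of two ≥ frame |
| mel filters | 128, 20–1000 Hz | one per output row; full preserved band |
| DCT | type II, orthonormal, all 128 kept | output rows = mel rows |
| log floor | 1e−10 | avoids log(0) on silence |

Clip-length presets (1/3/10 s) keep the frame length and change only
the hop so the frame count again tiles exactly (4/10/32 frames); each
pairs with a matching network-geometry preset.

The spectrum is a pure function of (samples, config): no dithering, no
padding, so identical input bytes give a bit-identical matrix.

## Network

The default ("5s") preset reproduces the reference capsule
architecture layer for layer; `NetworkConfig.shapes()` and
`count_params()` derive every output shape and trainable-parameter
count analytically (convolutions K²CF + F with valid padding and floor
division; digit capsules M·J·D_in·D_out per-pair weight matrices with
no bias — the bias-free form is forced by the printed 466,944 count;
decoder as a biased dense stack).

Open choices and how they were fixed:

- **Primary-capsule filter parametrization.** The second convolution's
  filter count is written as capsule_dim × channels (16 × 16 = 256 for
  the 5-s preset), the standard primary-capsule construction; this
  reconciles a "16" appearing in the per-preset settings with the 256
  conv filters of the full architecture table.
- **Decoder widths.** Only the decoder's parameter total and output
  shape are externally fixed. The stack 32 → 1024 → 2048 → 2048
  (ReLU, ReLU, sigmoid), with the 2048-unit output reshaped to
  128 × 16 × 1, reproduces the total exactly
  (33,792 + 2,099,200 + 4,196,352 = 6,329,344).
- **Margin-loss constants** m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 and the
  digitization threshold T = 0.5 are the canonical capsule-network
  defaults, exposed in `MarginLossParams`.
- **Routing order.** The coupled update equations are resolved in the
  standard order: couplings from current logits, then weighted sum and
  squash, then the agreement update — so with R = 1 the output is a
  uniform softmax-weighted average and no update ever affects it. The
  softmax normalizes over digit capsules j. The routing logits are
  bookkeeping, not parameters; gradients flow through the prediction
  vectors, with couplings treated as constants of each iteration.
- **Squash at both ends.** Primary capsules are squashed after the
  reshape and digit outputs are squashed again, as the layer
  definitions state; the degenerate single-capsule identity-weight case
  therefore yields squash(squash(ν)).
- **Reconstruction term.** Training optimizes margin loss +
  w_rec · MSE(reconstruction, scaled input), w_rec = 0.0005 by default;
  w_rec = 0 recovers pure margin-loss training. Histories always
  report the margin loss alone.
- **Initialization.** Seeded He-scaled normals for convolutions and the
  decoder, σ = 0.05 normals for the routing weight matrices. Two models
  built with the same seed are identical, which is what makes seeded
  `fit` runs reproducible.

### Autodiff backend

Gradients come from a bundled ~300-line reverse-mode engine
(`pcgcaps.autodiff`): broadcast arithmetic, matmul/einsum, strided
valid-padding convolution via im2col with a scatter adjoint, the usual
nonlinearities, and Adam. Every primitive's adjoint is checked against
central finite differences in the test suite. Float64 throughout —
accuracy over speed at these problem sizes.

## Training and evaluation

`TrainConfig` defaults mirror the reference setup: Adam at 0.0025, up
to 100 epochs, 5 routing iterations, batch size 8 (per-preset), and
three learning-rate policies:

- **plateau** (default): multiply by 0.15 after 3 consecutive epochs
  without validation-loss improvement. There is deliberately no lower
  bound, so on very small datasets (tens of clips) repeated drops can
  compound before convergence; use `fixed` or more data there;
- **decay**: start at 0.005, multiply by 0.1 at fixed intervals — the
  interval is nowhere specified externally, so it defaults to every
  30 epochs;
- **fixed**: constant.

The **early-stopping "15% gap"** is interpreted as a relative gap,
|val − train| / train > 0.15, which is scale-free across loss
magnitudes; an absolute mode is available via `early_stop_mode`. Best
validation-loss weights are restored at the end (restoring-best is
itself an open choice; it is the conservative one). Note the guard can
fire late in a healthy run once both losses are near zero and their
ratio becomes noisy — by then the classifier is converged, which is
the intended behavior of an overfitting guard, not a failure mode.

Inputs are min-max scaled to [0, 1] using training-set statistics
(stored with the checkpoint) so the sigmoid decoder's range matches its
target and optimization is well-conditioned.

Evaluation treats **normal as the positive class** (flip with
`positive_label`). The continuous score is the positive-class capsule
length; the confusion matrix digitizes it at T, precision/recall/
F1/accuracy plus abnormal precision and specificity are pure arithmetic
on the counts (zero denominators report as undefined, never 0), and the
ROC/AUC comes from sweeping the score threshold (scikit-learn
`roc_curve` + trapezoidal `auc`; the test suite cross-checks AUC
against the Mann–Whitney U formulation to 1e−9). Segment-level metrics
are primary; `aggregate_by_recording` offers majority voting per
recording but nothing depends on it.

## Synthetic phonocardiograms

`generate_recording` builds each clip as quasi-periodic cycles at a
heart rate drawn from 55–110 bpm with ±5% per-cycle jitter: a
Gaussian-windowed 70 Hz S1 burst at each cycle start, an S2 burst
(120 Hz, 0.8 relative amplitude) at 35% of the cycle, and — for the
abnormal class — band-passed (150–700 Hz, 4th-order Butterworth,
zero-phase) noise windowed between S1 and S2 at relative amplitude 0.4,
plus white noise at σ = 0.02 and final scaling to peak 0.95. The murmur
noise stream is drawn for both classes, so an abnormal clip with
murmur amplitude 0 is sample-identical to its normal counterpart — a
useful null control. Per-recording seeds spawn from the master seed, so
a dataset is reproducible byte for byte.

What it emulates: the spectral separation between classes, the
quasi-periodicity, the amplitude conventions, and variable heart rate.
What it does not: real murmur morphology (only systolic band-noise
murmurs; no diastolic, no clicks or splits), recording-chain artifacts,
sensor placement variability, pathological rhythm irregularity, or
class-conditional heart-rate differences. A band-energy threshold alone
separates the synthetic classes at ≥ 95% accuracy — by design, so that
learning tests are well-posed — which means passing them demonstrates
that the pipeline and optimizer work, not that the network would reach
any particular accuracy on clinical recordings.

## Problem sizes

The reduced "tiny" preset (32 conv filters, capsule dimension 8,
2 routing iterations, small decoder) is used for all learning runs:
400 training and 100 held-out spectra, ≤ 30 epochs, which converges to
≥ 90% held-out accuracy across seeds in well under a minute on one CPU.
The full 7.9M-parameter preset is exercised analytically (audit) and
for single forward passes; nothing in the package requires training it.

## Known limitations

- No heart-sound state segmentation (S1/systole/S2/diastole) and no
  denoising beyond anti-aliasing; whole clips are classified.
- Binary labels only; no murmur taxonomy.
- The numpy backend is single-threaded per operation and float64; it is
  sized for the reduced network, not for training the full preset at
  dataset scale.
- Checkpoints store raw float64 weights; they are not portable to other
  frameworks.
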