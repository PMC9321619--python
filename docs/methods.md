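# Methods

## Problem and model

`siamvitals` estimates two vital signs — heart rate (HR, beats/min) and
respiration rate (RR, breaths/min) — from facial video without skin contact.
Blood-volume pulses subtly modulate skin color (remote photoplethysmography,
rPPG), most strongly in the green channel; breathing modulates global
intensity and produces small facial movements. Two regions of interest (ROIs)
carry most of the usable signal: the forehead and the cheek (including nose
and mouth).

The model is a multitask Siamese convolutional network. The two ROI streams
pass through a *single* convolutional branch — the same layer objects process
both inputs, so weight sharing is structural rather than enforced by a
constraint — and each frame is reduced to a 48-dimensional embedding and then
a scalar. The two per-frame scalars are merged by elementwise addition into
the predicted PPG trace; no dense layer follows the merge on the PPG path.
In multitask mode a small per-frame dense head (embedding → hidden → scalar)
reads the *sum* of the two branch embeddings and emits the respiration trace.

Each branch stage is: 3×3 convolution → leaky ReLU (α = 0.01) → 1×1
channel-reduction convolution → leaky ReLU → channel attention → spatial
attention → 2×2 max pooling. The attention pair is the convolutional block
attention design: channel gates come from average- and max-pooled channel
descriptors pushed through one shared two-layer bottleneck (reduction ratio
8) and a sigmoid; spatial gates come from the stacked channel-mean and
channel-max maps convolved with a 7×7 kernel and a sigmoid. All gates are
strictly inside (0, 1).

Frames ride on the batch axis: all convolutions are 2-D and spatial, and both
output heads read out per frame. Consequences: output length always equals
the input frame count, and the parameter count is independent of clip length.
This is one of the two genuinely open architectural choices (the alternative
is 3-D convolution across time); the per-frame design was frozen because it
keeps the model small and length-agnostic, and because the rate extraction
stage supplies the temporal smoothing that convolutions across time would
otherwise provide.

The second open choice is the respiration head. A dense map from the merged
600-sample trace to a 600-sample trace would alone cost ~0.36 M parameters,
incompatible with the published size difference between the multitask and
single-task variants (~0.03 M); a per-frame multilayer head (48 → 588 → 1,
29,401 parameters) matches the budget exactly and preserves temporal
structure, so it is the default.

## Default architecture and parameter budget

The frozen full-size branch is:

| stage | operation | output channels |
|---|---|---|
| 1 | conv 3×3 + 1×1 + CBAM + pool | 32 → 16 |
| 2 | conv 3×3 + 1×1 + CBAM + pool | 32 → 16 |
| 3 | conv 3×3 + 1×1 + CBAM + pool | 32 → 163 |
| — | flatten (5×17×163) → dense | 48 |
| — | dense (PPG readout) | 1 |

Totals: 688,912 trainable parameters for the single-task (PPG-only) variant
and 718,313 with the respiration head — 0.69 M and 0.72 M at two printed
decimals. Shared branch parameters are counted once; `count_parameters`
deduplicates by object identity. The three dropout rates (0.25, 0.5, 0.6) are
assigned shallow-to-deep: after the last convolution stage, after the
embedding dense layer, and inside the respiration head.

A `reduced()` spec (12 h × 32 w ROIs, 128 frames, widths 8, embedding 16,
~3.7 k parameters) exists for desk-scale experiments and tests.

## Training

Loss per task is `1 − r(x, y)` with `r` the Pearson correlation between the
reference and predicted trace, computed per clip over all T samples; it is
bounded in [0, 2] and invariant to positive affine rescaling of the
prediction — the model learns waveform shape, not scale. The multitask total
is the unweighted sum of the PPG and respiration losses (weights are
configurable). A constant trace makes `r` undefined; the implementation
returns r = 0 (loss 1) with a degeneracy flag and a zero gradient, keeping
training alive on pathological batches.

Optimization is Adam (learning rate 1e-4, β₁ = 0.9, β₂ = 0.999), batch size
one (one clip per step), up to 250 epochs with the best-validation-loss
weights retained; "250 epochs" is treated as an upper bound, and optional
early stopping on validation patience is available and recorded. Clips are
split train:validation:test at 3:1:1 by a seeded shuffle with remainders
going to training. The network and its gradients are implemented directly on
NumPy arrays; with a fixed seed (shuffling, dropout, initialization) a run is
bit-reproducible.

## Rate extraction

Predicted (and reference) traces become rates in three deterministic steps:

1. **Bandpass** — Butterworth, applied forward–backward (zero phase, so peak
   instants are not delayed; the effective magnitude response is the squared
   design response). Cardiac: order 4, 0.66–3.3 Hz (40–198 BPM).
   Respiratory: order 2, 0.1–0.4 Hz (6–24 RPM). Edge transients are handled
   by scipy's default odd-reflection padding.
2. **Peak detection** — local maxima with minimum separation `1/high_hz`
   seconds and prominence at least 0.3 standard deviations of the filtered
   trace. These two thresholds are not dictated by the rate definition; they
   are documented defaults, overridable per call. Fewer than two peaks is an
   error, not a rate.
3. **Rate** — 60 divided by the mean inter-peak interval, which telescopes
   to `60 (N−1)/(p_N − p_1)`.

Paired predicted/reference rates are summarized by Pearson R, MAE and RMSE
(MAE ≤ RMSE always, by Jensen's inequality).

## Preprocessing of real video

ROI boxes are chosen once, from the first frame's 68-point landmarks
(landmarks come from a file or a pluggable callable; no detector ships).
Forehead: eyebrow extent horizontally, from the top of the face region to the
eyebrow line; since 68-point sets lack a hairline point, the top is the
landmark hull's top edge extended upward by 0.4× the eyebrow-to-chin
distance (configurable). Cheek: jaw-contour width, nose-tip line to chin
line. Boxes are clipped to the frame and held fixed for all frames; the
centered 600-frame window is selected; crops are resized to 40×140 with
bilinear interpolation and scaled to [0, 1] by the dtype maximum. Reference
traces are linearly interpolated to one sample per selected frame (whether
published pipelines decimated or interpolated is unstated; linear
interpolation is the documented choice here).

## Synthetic data: what it emulates and what it does not

The generator produces paired 140×40 forehead/cheek streams at 20 FPS, 600
frames, with per-frame truth. The cardiac truth is a fundamental sinusoid
plus a 0.3-amplitude second harmonic (normalized to [−1, 1]) — enough
asymmetry to exercise peak detection beyond a pure sine. It modulates pixel
intensity with green-dominant channel weights (0.4, 1.0, 0.5) at a relative
depth of 0.02 of the base color, about the small modulation depth real rPPG
exhibits while remaining recoverable after 8-bit quantization. The
respiratory truth is a sinusoid; how breathing manifests in facial video is
genuinely uncertain, so the simulator implements two switchable stand-in
mechanisms — a global intensity modulation (relative depth 0.04) and a ≤1 px
sinusoidal vertical translation of the vertical intensity gradient — without
claiming either is the physiological pathway. Nuisances: per-pixel Gaussian
noise (σ = 2 intensity units), a 0.03 Hz illumination drift (amplitude 1
unit, below both analysis bands), and 8-bit quantization with clipping.

Per-clip vitals in multi-clip simulations are drawn uniformly from resting
ranges: 0.8–2.0 Hz (48–120 BPM) and 0.15–0.35 Hz (9–21 RPM).

What passing tests on this data do **not** show: robustness to motion,
lighting changes, skin-tone diversity, compression artifacts, or any real
coupling between facial appearance and respiration. The generator defines a
controlled recoverability problem, not a benchmark of clinical accuracy.

## Scaled-down end-to-end study

The full-size configuration (600-frame clips, 0.72 M parameters) is too
large to train meaningfully on synthetic desk-scale data, so the end-to-end
acceptance study uses the reduced spec: 32 training clips (25% held for
validation) and 8 held-out test clips of 128 frames at 12×32 pixels, 40
epochs with the standard recipe. Reduced clips run at 8 FPS rather than 20:
a 128-frame clip must still contain at least two respiration cycles at the
slowest simulated rate (0.15 Hz needs ≥ 13.3 s) while the 3.3 Hz cardiac
band edge must stay below Nyquist (4 Hz at 8 FPS). Recovery quality is
measured as HR/RR MAE between rates estimated from predicted versus
ground-truth traces; the same seed reproduces the metrics bit-identically.

## Numerical choices and limitations

* Weight initialization is uniform fan-based (Glorot) from the spec seed.
* Max-pool and channel/spatial max gradients split ties evenly.
* Computation is float64 throughout; determinism relies on a fixed BLAS.
* The attention bottleneck uses leaky ReLU (α as everywhere) and biases.
* `pearson_r` clamps to [−1, 1] against rounding excursions.
* CPU-only and small by design: training the full-size spec on a real
  dataset is possible but slow; the package's training loop targets the
  reduced configurations.
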