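# Methods

This note documents the models, conventions and design choices behind
`rppgnet`: what is computed, which parameters matter, what the synthetic data
does and does not emulate, and where the genuinely open decisions were made.

## The network

The model maps a video volume `(3, T, H, W)` — RGB, nominally 30 fps, face
crops resized to 128 × 128 — to a real-valued trace of length `T`, one rPPG
sample per frame.

**Encoder.** A 3 × 3 × 3 stem convolution (stride 1 × 2 × 2) is followed by
eleven inverted-residual blocks. Each block expands channels with a
point-wise (1 × 1 × 1) convolution, filters with a depth-wise 3-D convolution
(kernel 3³ or 5³, per-channel), applies an optional shuffle-attention block,
and projects back down with a linear point-wise convolution; an identity
skip is added when the stride is 1 × 1 × 1 and input and output widths match
(the mobilenet-v2 rule — the compressed representation carries the residual).
Strides are read as (temporal, height, width); this is the only reading
consistent with the printed shape progression. The temporal axis is halved
twice in the encoder (T → T/2 → T/4); spatial extent is halved five times.
Every convolution is followed by batch normalization; nonlinearities are
ReLU6 in the stem and first three blocks and h-swish
`x · ReLU6(x + 3)/6` thereafter, the usual efficiency compromise for
sigmoid-shaped gates.

**Shuffle attention (3-D).** The feature volume is split into `G` groups of
channels; each group is halved into a channel branch and a spatial branch.
The channel branch gates each channel by
`sigmoid(w · GAP(x) + b)` where GAP is the mean over the full
T × H × W extent; the spatial branch normalizes each channel to zero
mean/unit variance over its T × H × W extent (per-channel group
normalization, epsilon 1e-5, with a learnable affine) and gates voxel-wise by
`sigmoid(w · GN(x) + b)`. Branches are re-concatenated and channels shuffled
by the reshape-(G, C/G)-transpose-flatten permutation so information flows
across groups. Output shape always equals input shape, so the block is
insertable anywhere.

Open parameters here — the group count `G` and the granularity of the group
norm — are not fixed by the architecture description. Defaults: `G = 4`,
clamped automatically to the largest divisor of `C` that keeps both branches
non-empty; per-channel normalization (group count = sub-feature width),
matching the 2-D shuffle-attention design this block generalizes. The gate
parameters initialize to `w = 0, b = 0` for the channel branch and
`w = 1, b = 0` for the spatial branch, so a fresh block is near-neutral
(every gate ≈ 1/2 up to the GN shape) and early training is stable.

**Temporal decoder.** Two decoder blocks restore the temporal length
(T/4 → T/2 → T). Each applies a *depth-wise* transposed convolution along
time only (kernel (4, 1, 1), stride (2, 1, 1), padding (1, 0, 0) — exactly
2× upsampling), then a point-wise projection halving the channel count
(576 → 288 → 144), each convolution followed by batch norm and h-swish.
Making the decoder separable rather than a dense transposed convolution is
this package's own design choice, consistent with the separable-convolution
theme of the rest of the network; it is also what brings the parameter total
in line with the published aggregate (a dense temporal transposed
convolution at 576 → 288 channels alone would cost 0.66 M parameters — see
"Complexity accounting" below).

**Recurrent head.** Three stacked ConvGRU layers (hidden width 64, 2-D
kernels 3 × 3 with zero padding so the hidden state keeps the 4 × 4 feature
geometry) consume the decoder output frame by frame:

    z_t = σ(Wz * x_t + Uz * h_{t−1})
    r_t = σ(Wr * x_t + Ur * h_{t−1})
    h̃_t = tanh(W * x_t + U * (r_t ⊙ h_{t−1}))
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t

With 1 × 1 kernels on a 1 × 1 grid this reduces exactly to the dense GRU,
which the tests use as an independent oracle. The three layers' hidden-state
sequences are fused by an elementwise mean: the architecture table reports a
single 64-channel recurrent output, which rules out concatenation (192
channels), and a sum differs from a mean only by a scale the following
convolution absorbs. No normalization is used inside the recurrence. Gate
biases start at zero; kernels use seeded He initialization.

Finally spatial global average pooling collapses H × W to 1 × 1 (temporal
axis preserved) and a 1 × 1 × 1 convolution with bias — and deliberately no
nonlinearity, since rPPG values are unconstrained in sign — emits the trace.

**Input contract.** T must be divisible by 4 (two temporal halvings must
invert exactly) and H, W by 32; violations raise an error naming the
offending dimension.

## Training

Loss: mean over the batch of `1 − r(pred, target)` per clip, where `r` is
the sample Pearson correlation — scale- and offset-invariant, 0 at perfect
correlation, 2 at perfect anti-correlation. The training form adds 1e-8
inside the square roots so a momentarily flat prediction does not produce a
NaN; the strict analysis-mode functions instead raise on zero variance.

Protocol defaults (all configurable in `TrainConfig`): Adam, learning rate
1e-3 multiplied by 0.1 every 10 epochs, 30 epochs, batches of 8 clips of 128
frames sliced at stride 8. Each clip's target window is band-pass filtered
(0.5–4 Hz) and z-normalized. Video clips are standardized to zero mean/unit
variance before entering the network. All randomness (init, shuffling,
synthesis) flows from explicit seeds.

The tensor engine underneath is a ~500-line reverse-mode autodiff over numpy
arrays: grouped 3-D convolution (lowered to `sliding_window_view` + einsum,
with a batched-matmul fast path for 1 × 1 × 1 convolutions), a
zero-interleaving primitive that expresses strided transposed convolution as
dilation + correlation with the flipped kernel, the elementwise and
reduction ops the network needs, and an Adam implementation. Every
primitive's gradient is checked against central finite differences in the
test suite.

## Signal processing and HRV

- **Band-pass**: linear-phase FIR (Hamming window), order ≈ 3·rate/f_lo
  (capped so forward–backward filtering stays well-posed on short records),
  applied with `filtfilt` so net phase is zero — HRV depends on peak timing,
  and a causal filter would shift every beat. Reference PPG uses 0.5–4 Hz
  (keeps the second harmonic); recovered rPPG uses 0.5–3.5 Hz before peak
  detection.
- **Resampling**: cubic splines, both for rate conversion (e.g. 30 Hz) and
  for the 256 Hz upsampling before peak detection (beat-timing precision of
  ±1 sample then means ±3.9 ms).
- **Peak detection**: local maxima with a refractory distance of
  rate/f_max (f_max = 2.5 Hz, the top of the normal heart-rate band) and a
  prominence threshold of 0.3 × trace standard deviation; the first and last
  second are excluded to avoid filter transients. The detector is
  deterministic and fully configurable; no beat-interval outlier rejection
  is applied by default (a physiologic 250–2000 ms band filter is available
  behind a flag).
- **Time-domain metrics** use the standard definitions (squared deviations
  inside SDNN, T−1 successive differences in RMSSD with a T−1 denominator).
- **Frequency-domain metrics**: the NNI series is anchored at the time of
  each interval's closing beat, spline-resampled to a uniform 4 Hz grid,
  mean-removed, and fed to Welch's method (Hann window, 64 s segments or
  the whole record if shorter, 50% overlap). LF = 0.04–0.15 Hz,
  HF = 0.15–0.4 Hz, integrated by the trapezoid rule; reported as
  LFnu = LF/(LF+HF), HFnu = HF/(LF+HF) (summing to 1 by construction) and
  LF/HF. Records shorter than 30 s are rejected — the LF band cannot be
  resolved. These estimator choices are the conventional ones; the source
  architecture description does not pin them down.

## Synthetic data

The generator produces the statistical structure the method assumes, with
exact analytic ground truth:

- Instantaneous heart frequency
  `f(t) = f0 (1 + a_LF sin 2π f_LF t + a_HF sin 2π f_HF t)` with defaults
  f0 = 1.2 Hz (72 bpm), f_LF = 0.1 Hz, f_HF = 0.25 Hz, depths 0.05. The
  cumulative phase Φ(t) is available in closed form, so beat times — defined
  as the crossings Φ ≡ π (mod 2π), the phase at which the two-harmonic pulse
  template `−cos Φ + 0.3 cos 2Φ` attains its maximum — are root-refined to
  1e-9 s, not grid-snapped. Anchoring beats at the template maximum (rather
  than Φ = 0) keeps the analytic truth exactly aligned with what a peak
  detector can observe; under frequency modulation the two differ by up to
  ~10 ms. The tachogram this induces has components at f_LF and f_HF with
  amplitudes ∝ a_LF, a_HF, so the expected normalized LF power is
  `a_LF²/(a_LF² + a_HF²)`.
- Video: an elliptical "face" of skin-toned pixels on a dark background;
  within the ellipse, channel intensities are offset by
  pulse-amplitude × waveform × (0.4, 1.0, 0.6) for R, G, B — the
  green-dominant pulsatility of real skin. Nuisances: global sinusoidal
  illumination drift, per-pixel Gaussian noise, and per-frame translation
  jitter of the face (the true box is recorded per frame). Values clip to
  [0, 255]; a warning is logged if clipping touches more than 1% of skin
  pixels.
- All randomness derives from one seed; the dataset manifest records every
  per-clip parameter for exact regeneration.

What this does **not** emulate: photorealistic facial appearance and
texture, head rotations and expression changes, camera compression
artifacts, specular highlights, and realistic skin-tone diversity. Passing
tests on this generator therefore demonstrate that the pipeline is correct
and self-consistent (signal present → signal recovered, with exact beat
accounting); they do not demonstrate accuracy on real recordings, which is
a dataset-scale benchmark question out of scope here.

## Complexity accounting

The profiler counts one unit per multiply–accumulate, for convolutions,
transposed convolutions and the six convolutions per ConvGRU layer only —
the multiplications-only convention of the separable-convolution cost
formulas (`Dk³Dg²MNT` standard; `Dk³Dg²MT + Dg²MNT` separable; ratio
`1/N + 1/Dk³`). Normalization, nonlinearities, pooling and attention gating
are excluded from MACs but their trainable parameters (batch-norm affine,
attention scale/shift and GN affine) are counted. Convolutions followed by
batch norm carry no bias; the output convolution and the ConvGRU input
convolutions do.

At the nominal input 1 × 3 × 128 × 128 × 128 the defaults give
**4.374 GMACs** and **1.720 M parameters**, with the recurrent head
dominating compute (1.64 GMACs) and the decoder dominating parameters.
These are within 7% of the published aggregates (4.69 G / 1.62 M); the
residual is attributable to counting-convention ambiguity (what the original
FLOP counter included) and to the decoder structure, which the source table
specifies only as "DCBlock, 4 × 1 × 1". The per-layer table
(`rppgnet profile --out table.csv`) itemizes every row so the discrepancy is
inspectable rather than hidden.

The profiler's parameter total is asserted equal to the instantiated
model's trainable-entry count in both the test suite and the acceptance
script — the closed form and the implementation cannot drift apart
silently.

## Numerical choices and degenerate inputs

- Batch norm uses batch statistics in training mode (momentum 0.1 running
  stats for inference), epsilon 1e-5.
- Pearson computations clip to [−1, 1] against rounding; constant series
  raise a degenerate-input error in analysis mode.
- Peak detection on a constant trace returns an empty peak set (the caller
  decides); fewer than two peaks raises an insufficient-beats error on NNI
  extraction.
- Cubic-spline resampling requires ≥ 4 samples; band-pass cutoffs must lie
  strictly inside (0, Nyquist).
- Inference stitching for videos longer than one 128-frame window uses
  non-overlapping windows plus a right-aligned tail window; each window's
  output is z-normalized before stitching (the correlation loss leaves
  per-window scale arbitrary, so stitching raw amplitudes would be wrong)
  and the tail overlap is averaged.
- Videos at other frame rates should be resampled to 30 fps before slicing;
  the pipeline assumes one-to-one frame/target correspondence and checks it.

## Problem sizes used in the test suite

The suite exercises the full 128-frame, 128 × 128 shape contract in a single
forward pass, and demonstrates training convergence by overfitting one
synthetic 64-frame 64 × 64 clip for 200 iterations (negative-Pearson loss
falls below 0.3, i.e. r > 0.7 against the reference). Dataset-scale training
runs (30 epochs over full recordings) use the same code path and are left to
the user.

## Known limitations

- The original normalization scheme, shuffle-attention group count and
  decoder internals are not fully specified upstream; the conventions above
  are this package's, and the complexity figures shift at the percent level
  under alternative readings.
- A real face detector (e.g. MTCNN) is deliberately out of scope; the
  detector interface accepts any callable, and built-in detectors cover
  full-frame and known-box (synthetic) cases.
- numpy-based training is CPU-bound and suited to small studies and tests,
  not GPU-scale benchmark reproduction.
- No beat-morphology analysis (slope-sum, wavelet denoising) and no
  nonlinear or 24-hour HRV indices (pNN50, SDANN) are provided.
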