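# Methods

## Problem and pipeline

`emaseg` measures the eye-muscle area (EMA) — the cross-section of the
longissimus dorsi — from B-mode ultrasound stills of live sheep.  The
pipeline has four stages: preprocess a grayscale frame to a square model
grid, segment the muscle with a state-space U-shaped network, count
foreground pixels in the predicted binary mask and convert them to mm² with
the device calibration, and compare automated areas against reference
(expert) areas with agreement statistics.

## Network

The segmentation model is a five-stage encoder/decoder.

**Encoder.** A 7×7 stride-2 convolutional stem with instance normalization
produces the first pyramid level (width `b`, default 48).  A 2×2
convolutional patch embedding and three 2×2 patch-merging layers halve
resolution and double width up to `16b` (768), each followed by a stage of
VSS (visual state-space) blocks.  A VSS block is a two-branch gated unit: a
linear/SiLU gate multiplies the output of a depthwise-conv → SiLU → SS2D
branch, with a residual connection.  SS2D flattens the feature map in four
traversal orders (row-major and column-major, each forward and backward) and
runs each sequence through a selective state-space recurrence

    h_t = exp(Δ_t A) h_{t−1} + (Δ_t B_t) x_t ,   y_t = C_t·h_t + D x_t ,

where Δ (via softplus), B and C are projected from the input per direction,
`A = −exp(A_log)` is negative real (stable contraction), and the four
direction outputs are summed and layer-normalized.  Internals follow the
usual tiny-backbone configuration: state dimension 16, expansion 2,
`dt_rank = C/16`, Δ bias initialized log-uniform in [1e−3, 1e−1].  No
positional embeddings are used.  Because the paper-listed block counts name
five entries for four post-stem stages, the default is 2 blocks in each of
the four stages, configurable.

**Skip connections (MSEE).** Each skip is refined by two parallel paths.
The context path sums a 1×1 convolution with three 3×3 dilated convolutions
(rates 6/12/18), layer-normalizes, forms Q/K/V with
pointwise∘depthwise convolutions, and applies transposed (channel-to-channel)
attention — the C×C Gram matrix of K and Q, softmax over its last axis with
a learnable scalar temperature (init 1) — followed by a 1×1
depthwise-separable projection.  The edge path applies a fixed depthwise
Sobel operator (gradient magnitude, replicate padding so constants respond
exactly zero), batch-norm, ReLU, a 3×3 depthwise-separable convolution, adds
the input residually and projects 1×1.  The module output is the sum of the
two paths.

**Bottleneck (PARM).** Adaptive average pooling onto 1/3/5/7 grids,
bilinear upsampling, and concatenation with the input form a 5C context
stack.  Query and key are 1×1-compressed (C′ = C/4) from the stack, the
value from the raw input; non-local attention over all position pairs runs
independently on 4 channel groups; a final 1×1 convolution restores C and
the input is added residually (zeroing that convolution gives an exact
identity).  Since a 128-px input leaves a 4×4 bottleneck, the reduced
profile uses pooling grids (1, 3).

**Decoder (GCAD).** Each stage upsamples 2× with channel halving — a 2×2
stride-2 transposed convolution implemented exactly as a 1×1 convolution to
4× width plus depth-to-space — concatenates the edge-enhanced skip, fuses
1×1 to the stage width (384/192/96/48 at base 48) and refines with a GCAD
block: `XA = Norm(X); XS1 = XA + Norm(MCA(XA)); Y = XS1 + MLP(XS1)` with a
pointwise ×4 GELU MLP.  MCA aggregates hierarchically with three dilated
depthwise-separable 3×3 convolutions (rate 6 feeding 4 feeding 2, each given
the input plus the previous branch), a 3×3 stride-1 average-pooling branch
(count-normalized at borders so constants are preserved; a global pool would
not be shape-compatible with the F1+F4 addition), concatenates to 4C and
gates multiplicatively with two independently parameterized 1×1+SiLU paths.
A final 2× expansion and 1×1 convolution give single-channel logits;
probabilities are logistic, thresholded at 0.5.

**Loss.** `L = L_Dice + L_BCE`, equally weighted.  Dice uses smoothing 1e−5
in numerator and denominator (the bare ratio is undefined for empty masks)
and is averaged per image; BCE clips probabilities to [1e−7, 1−1e−7].

**Training.** AdamW (lr 1e−4, weight decay 5e−2), batch 12, 50 epochs,
constant learning rate, no early stopping in the full profile; history CSV
records per-epoch mean train/val loss and validation Dice; the checkpoint
with the best validation Dice is kept.  Augmentation (training only):
rotation ±30° (p 0.2), scaling 0.7–1.4 (p 0.2), elastic deformation (p 0.2,
amplitude 10 px, smoothness 8 px), brightness ×0.75–1.25 (p 0.15), contrast
×0.75–1.25 (p 0.15), additive Gaussian noise σ ≤ 0.1 (p 0.1).  Geometric
transforms are shared between frame and mask (mask nearest-resampled);
intensity transforms touch the frame only; validation/test inputs are never
augmented.

## Numerical engine

No GPU framework is used: the network runs on a small reverse-mode autodiff
engine over numpy (`emaseg.nn`), float32 by default.  Convolutions loop over
kernel taps and contract with einsum; adaptive pooling and bilinear resizing
are dense separable matrix operators (hence exactly linear and trivially
differentiable).  The selective scan is a single fused graph node: forward
runs the recurrence blockwise using the identity
`h_t = exp(S_t)(h_0 + Σ_{s≤t} exp(−S_s) B̄x_s)`, `S = cumsum(ΔA)`, whose
within-chunk exponents are bounded by `chunk·max|ΔA|` (chunks escalate from
float32 to float64 arithmetic when that bound nears the float32 exponent
range); backward solves the time-reversed adjoint recurrence with the same
blocking.  A literal per-timestep sequential implementation ships alongside
as the correctness oracle, and the test suite pins agreement to 1e−5.

## Synthetic phantoms

The study's animal images are private, so every stage is exercised on
synthetic B-mode-like phantoms.  The muscle cross-section is a filled,
rotated superellipse (exponent 1.5–3, axis ratio 0.55–0.8) whose target area
is sampled from the reference population span 356–1490 mm²; the intensity
model is a mid-grey background (0.45), darker interior (0.22) and bright,
partially broken echogenic rim (0.85, width 2 px), optional bright streak
artifacts, Gaussian boundary feathering (σ 1 px), and multiplicative
unit-mean Gamma speckle (strength 0.35) with a light blur — a desk-scale
surrogate for fully developed speckle.  Defaults are 128×128 px at 0.7 mm/px
(the calibration of the study device is unpublished, and 0.7 mm is the
smallest isotropic spacing whose 89.6 mm field admits the largest sampled
cross-section); 512×512 is supported.  Phantoms are deterministic given a
seed, and the paired mask yields an exact area record.

What the phantoms do not emulate: acoustic shadowing and attenuation,
anisotropic point-spread functions, real tissue texture, inter-operator
variability, or ambiguous anatomy.  Passing tests therefore demonstrate that
the implementation is correct and trainable in a controlled low-SNR regime,
not that field performance on clinical images is attained.

## Scaled-down experiments and problem sizes

CPU suites use a reduced named profile: base width 16 (channels 16→256),
one VSS block per stage, 128-px inputs, pooling grids (1, 3), batch 4,
learning rate 1e−3 (small-sample overfitting converges reliably at this
rate; the full profile keeps 1e−4).  The capability experiment trains this
profile on 8 phantoms for at most 300 optimization steps (stopping early
once training Dice reaches 0.95, checked every 10 steps) and then requires
training-set Dice ≥ 0.90 and per-image IoU ≥ 0.8 through the full `predict`
path.  With the pinned seeds this converges in roughly 60 steps.

## Numerical choices and degenerate inputs

* Metric ratios with zero denominators return 1.0 when the numerator
  condition is vacuously perfect (e.g. recall with no reference positives
  and nothing predicted), else 0.0.
* HD95 is the 95th percentile (linear interpolation) of the pooled
  bidirectional boundary-distance multiset, boundaries extracted by
  8-connected erosion difference, distances under anisotropic mm spacing;
  empty masks raise an explicit error rather than returning infinity.
* Pearson r of two identical series is reported as 1.0 with a
  `r_degenerate` flag (the formula is 0/0); a constant-but-unequal series
  raises.
* Agreement errors are unit-tagged (`px` or `mm2`) and never silently mixed.
* Dataset splitting assigns `floor(n·ratio)` per subset with the remainder
  to the training set; with n = 710 and ratios 7:2:1 this is exactly
  497/142/71.
* Masks serialize as {0,255} PNG, read back with threshold 128.

## Known limitations

* CPU-only: full-size (512 px, base 48) training is supported but slow; the
  package targets correctness and desk-scale experiments, not throughput.
* The full-size configuration has 29.9 M parameters.  The equations
  describing the modules — depthwise-separable convolutions and 1×1
  projections throughout — cannot reach the 61 M scale reported for the
  original model, whose decoder composition is not documented at that level
  of detail; widths here follow the written description rather than the
  parameter table.
* Pretrained-backbone loading is an optional interface
  (`Module.load_state_dict` with shape checks); no weights are bundled or
  downloaded.
* Significance testing between competing models is out of scope (no test is
  specified for the published comparisons), as are ICC-style error
  decompositions.
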