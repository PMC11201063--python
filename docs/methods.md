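# Methods

## Model

The network is a five-stage U-shaped encoder–decoder for binary polyp
segmentation. Stage widths are {16, 32, 64, 128, 128}; a 2×2 max-pool
precedes stages 2–5, so the bottleneck sits at 1/16 resolution and inputs
must have sides divisible by 16. Stage 1 is a residual double 3×3 conv
block (BN + ReLU, 1×1-projected skip); in the full model stages 2–5 are
fusion-attention encoder stages, the four skip connections carry visual
attention Mamba modules, and the bottleneck applies pyramid split
attention. The decoder is four blocks of bilinear 2× upsampling, skip
concatenation and a residual double conv; a 1×1 convolution with a sigmoid
emits one foreground-probability channel. Six variants (plain baseline,
encoder without/with the channel gate, skips only, encoder+skips, full)
isolate each contribution.

**FAEncoder.** Input is lifted by a 3×3 conv (BN+ReLU) to the stage width.
Branch 1: 1×1 conv → GELU → LKA → 1×1 conv; branch 2: 1×1 conv. LKA builds
an attention map with a 5×5 depth-wise conv, a 7×7 depth-wise conv with
dilation 3 and a 1×1 conv, and multiplies it with its input. The exact
support of that composition around an impulse is 23×23 (5 + 6·3); "21×21"
is the nominal kernel the decomposition approximates, and the tests assert
the exact 23. Branch outputs are added, mixed by a 3×3 conv (BN+ReLU) and
gated by squeeze-excitation channel attention. The 1×1 convs are
width-preserving (no hidden expansion), keeping the stages light.

**VAM.** The skip feature map (B, C, H, W) is flattened in raster order to
(B, L=H·W, C), layer-normalised and passed through a gated selective-scan
block with the standard Mamba parameterisation: expansion λ=2, state
dimension N=16, Δ-projection rank ⌈C/16⌉, causal depth-wise 1-D conv of
kernel 4, A initialised to −(1…N) per channel, D=1, Δ bias initialised so
softplus lands log-uniformly in [1e-3, 0.1]. The scan is a single forward
raster pass (no bidirectional variant). Operator order follows the
equation form: 1-D conv → SiLU → SSM → LayerNorm, gated by SiLU(Linear)
and projected back to C. The reshaped result is concatenated with a 1×1
branch, fused by a 1×1 conv and recalibrated by channel then spatial
(CBAM-style 7×7 on per-pixel mean/max) attention. VAM is applied to all
four skip levels, including the stage-1 skip.

**PSA.** The bottleneck's 128 channels feed S=4 parallel group
convolutions with kernels K_i = 2(i+1)+1 = 3/5/7/9, each emitting C/S=32
channels. Per-branch squeeze-excitation logits are normalised by a softmax
*across branches* independently per channel slot; each branch map is
scaled by its weight and the maps are concatenated back to 128 channels.
Two branch-input conventions are implemented: `full` (every branch reads
all C channels; groups 1/4/8/16 — the reference implementation's
convention, and the calibrated default) and `split` (branch i reads only
its C/S chunk with groups 2/4/8/16 per the formula G_i = 2^((K_i−1)/2) —
the textual description). See "Calibration" for why `full` is the default.

## Runtime

No deep-learning framework is used: the package ships a small reverse-mode
autodiff engine over numpy (`lightcf.nn`). Convolutions are stride-1 and
implemented as channels-last im2col plus a single BLAS matrix product, with
an explicit backward; depth-wise and grouped convolutions use a
shift-and-accumulate path. The selective scan's forward and backward
recurrences are hand-derived and numba-compiled; an O(L·N) pure-python
recurrence serves as the independent oracle in the tests, and every
structured op is checked against finite differences in float64.
Training-mode batch norm is a fused primitive with the closed-form
gradient. Default arithmetic is float32; tests that need tight tolerances
switch the engine to float64.

## Loss, metrics, protocol

The loss is per-pixel-mean binary cross-entropy (predictions clamped to
[1e-7, 1−1e-7]) plus the smoothed Dice complement with σ=1. The mean BCE
(rather than the literal sum) keeps the loss scale resolution-independent;
`bce_reduction="sum"` restores the literal form. Metrics are the standard
confusion-matrix forms (IoU, DSC, sensitivity, specificity, accuracy, as
percentages; empty ground truth with empty prediction scores 100 by
convention), binarised at 0.5; AUC is the pixel-level Mann–Whitney
statistic (via scikit-learn), pooled over images. Test-set aggregation
averages per-image metrics (the dominant convention in this literature),
not pooled confusion counts.

Training uses Adam with weight decay 1e-5, batch size 8, poly decay
lr = 0.001·(1 − epoch/max_epoch)^0.9 stepped per epoch (the schedule is
epoch-indexed), max_epoch 200, horizontal/vertical flips and rotations
uniform in [−90°, 90°] (bilinear for images, nearest for masks), and the
320×320-resize → random 256×256-crop input protocol for real datasets.
Runs are fully seeded; identical seeds give identical loss curves.

## Calibration of open internals

The published ablation table fixes the parameter budgets (in millions):
baseline 0.97, +FAEncoder_w/o_CA 1.15, +FAEncoder 1.16, +VAM 1.21,
+FAEncoder+VAM 1.40, full 1.52. The decoder composition, channel-attention
reduction, PSA conventions and Mamba internals are not stated, so they
were fixed by a closed-form count search over: decoder conv forms (single
3×3, double 3×3, 1×1+3×3, with/without residual projection), decoder
widths, encoder residual projections, channel-attention reduction r ∈
{4, 8, 16}, VAM levels, and the PSA branch-input/groups conventions. The
shipped `reference.yaml` records the selected configuration: residual double
convs with projections everywhere, decoder widths (64, 64, 32, 16),
r = 4 (bottleneck width floored at 4), VAM with Mamba defaults on all four
skips, PSA in full-input mode with groups (1, 4, 8, 16).

This yields 0.971 / 1.140 / 1.159 / 1.214 / 1.401 / 1.512 M — exact at two
decimals for baseline, +FAEncoder, +VAM and +FAEncoder+VAM, and within 1%
for the other two. No configuration in the searched space reproduces all
six printed values simultaneously: the printed deltas (+0.18 to the
gate-less encoder, +0.01 for the gate, +0.24 for the skips) are mutually
inconsistent with any single additive decomposition at two decimals, so
the two mismatches are accepted and the strict ordering of the table is
asserted instead. The `split` PSA convention would put the full model at
1.43 M — far from the printed 1.52 — which is why the reference
implementation's full-input convention is the calibrated default.

## Synthetic data

The generator produces seeded colonoscopy-like fixtures: multi-octave
value-noise mucosa texture around a pale-pink base, a directional-plus-
vignette illumination field, 1–3 polyps as ellipses (aspect 0.6–1.0) whose
boundaries are perturbed by random radial cosine harmonics (orders 2–5,
total relative amplitude 0.22), a low-contrast polyp tint (default 0.25,
randomly darker or lighter), 2–6 small specular highlights and Gaussian
sensor noise (σ = 2% of full scale). Radii span 6–22% of the image side.
Masks are the exact rasterised polyp support. Every sample is a pure
function of (config, index).

What this emulates: the challenge axes of real endoscopy (size/shape/
colour variability, low lesion contrast, uneven lighting, glare). What it
does not: real mucosal texture statistics, motion blur, fluids, instrument
occlusion, annotation noise. Passing tests therefore demonstrate that the
architecture, losses, metrics and training loop are correct and that the
network can fit segmentable structure; they say nothing quantitative about
accuracy on real colonoscopy data, which requires the public benchmarks.

## Problem sizes

CPU-friendly sizes are used throughout: the smoke training run overfits
eight 128×128 fixtures for 200 optimiser steps with the baseline variant
(reaching DSC ≥ 90% on its training frames); oracle suites use sequences
of length ≤ 20, state dimension ≤ 4 and maps ≤ 11×11; forward-contract
checks cover 256², 320², 288×384 and 480² inputs. The full-scale profile
(256×256 crops, 200 epochs, full variant) is configured in `reference.yaml`
and runs unchanged on larger hardware.

## Numerical choices and edge cases

- Attention gates are sigmoids, hence strictly inside (0, 1); the final
  probability map may round to exactly 0 or 1 in float32.
- Max-pool ties resolve to the first maximum (raster order).
- Bilinear resampling uses the half-pixel-centre convention.
- The scan rejects non-positive step sizes; softplus guarantees Δ > 0 in
  the block itself.
- Empty ground truth: IoU = DSC = 100% when the prediction is also empty;
  AUC raises on single-class ground truth.
- Checkpoints are a `.npz` weight archive plus the YAML config that built
  the model; loading verifies config/weight compatibility and reports the
  offending keys.

## Limitations

- CPU-only and optimised for clarity over throughput; full-scale training
  (200 epochs at 256²) is impractical on one core.
- FLOPs/FPS claims of the original ablation are hardware- and
  convention-bound and are not reproduced; only parameter counts are.
- The two ablation rows that do not match at two decimals (gate-less
  encoder 1.14 vs 1.15, full 1.51 vs 1.52) reflect the calibration
  analysis above.
- Single forward raster scan in VAM; no bidirectional or cross-scan
  variants.
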