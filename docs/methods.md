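# Methods

`ctsr` super-resolves single CT slices: given a low-resolution (LR) image
it reconstructs a high-resolution (HR) image at an integer scale factor
r ∈ {2, 4}. The LR inputs are produced from HR references by bicubic
downsampling, so the network learns to invert a known, fixed degradation —
the standard bicubic-degradation protocol of the single-image
super-resolution literature.

## Model

The network has three parts:

1. **Low-frequency feature extraction** `H_LF`: a 3×3 convolution, a 1×1
   convolution, and a 3×3 convolution, mapping the image to `embed_dim`
   channels at LR resolution (`F₀ = H_LF(I_LQ)`). This shallow path
   captures flat-area content.
2. **Deep feature extraction** `H_DF`: a sequence of `num_atbs` attention
   transformer blocks (ATBs). Each ATB applies `stls_per_atb` swin
   transformer layers (STLs) followed by a 3×3 convolution and a
   block-level residual: `F_out = conv(STL_L(…STL_1(F_in))) + F_in`. Each
   STL is a pre-norm transformer block over M×M windows:
   `X ← X + MSA(LN(X))`, then `X ← X + MLP(LN(X))`, where the MLP is
   linear(C → mlp_ratio·C) → GELU → linear(→ C) applied per position.
3. **Reconstruction** `H_REC`: acting on the sum `F₀ + F_DF`, a 3×3
   convolution to 64·2² channels, a ×2 pixel shuffle to 64 channels
   (repeated twice for scale 4), and a final 3×3 convolution back to the
   image channels. The `F₀` skip carries low frequencies directly to the
   head, so the transformer stack concentrates on high-frequency detail.

### Windowed attention

Feature maps are cut into non-overlapping M×M windows ((H·W)/M² windows of
M² tokens) and multi-head self-attention runs independently per window:
`softmax(QKᵀ/√d_head + B + mask)·V`, heads concatenated and projected.
`B` is a learnable relative-position bias, one scalar per head for each of
the (2M−1)² in-window offsets (switchable via `use_rel_bias`; enabled by
default, the established choice for window attention even though it is an
extension of the bare attention formula). Odd-indexed STLs cyclically
shift the map by ⌊M/2⌋ before partitioning so neighbouring windows
communicate; tokens that were not spatial neighbours before the shift are
decoupled with an additive mask of −1e9 on their logits (finite rather
than −∞ so the softmax stays well-defined; the resulting cross-region
attention mass is below 1e−12). Maps not divisible by M are reflect-padded
before partitioning and cropped after merging; the pad/shift/partition
pipeline is exactly invertible.

### Defaults and their origin

| parameter | default | origin |
|---|---|---|
| num_atbs | 6 | published configuration |
| stls_per_atb | 6 | published configuration |
| window_size M | 8 | published configuration |
| scale r | 2 | published worked example (×4 = two ×2 stages) |
| embed_dim | 60 | unstated; chosen CPU-trainable, divisible by heads |
| num_heads | 6 | unstated; standard for this width |
| mlp_ratio | 2.0 | unstated; common lightweight choice |
| head width | 64 channels after shuffle | published reconstruction block |
| MLP nonlinearity | GELU | unstated ("nonlinear transformation"); transformer default |
| attention scale | 1/√d_head | unstated; standard |
| shift schedule | 0, ⌊M/2⌋ alternating | unstated; the established convention |

Weight init: truncated normal (σ = 0.02, clipped at ±2σ) for attention and
MLP weights, uniform ±1/√fan_in for convolutions, all driven by
`init_seed`. Layer normalization acts over the channel axis per token
(ε = 1e−5).

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with the published schedule: initial
learning rate 2×10⁻⁴ multiplied by 0.999 after every update
(`lr(k) = 2e−4 · 0.999^k`). Loss is mean absolute error (L1) by default —
the norm for transformer SR and stable at small batch sizes — with an MSE
switch. Gradients are clipped at global norm 1.0 as a guard against rare
large logits on the masked-attention path. Batches are `batch_size`
LR-aligned patch pairs sampled uniformly from the training images,
augmented with a uniform draw from the 8 dihedral transforms applied
identically to both members. Validation PSNR is computed every
`val_every` updates; the best-validation checkpoint is kept, and `last.npz`
(weights + optimizer moments + step) makes runs resumable.

Patch size: the published protocol uses 48×48 LR patches. The desk-scale
default here is smaller (see `TrainConfig.patch_size`), chosen so the
reference study (2,000 updates, batch 8) completes in minutes on one CPU
core; the patch must be a multiple of the window size so STLs run unpadded
during training. The full-size value remains available through the config.

## Degradation pipeline

HR → LR uses bicubic resampling in the Catmull-Rom (a = −0.5) dialect with
an antialias prefilter on downscale (Pillow's implementation); the dialect
string is written into run provenance because resizer implementations
differ measurably. Images are held as float32 in [0, 1]; the source bit
depth travels alongside for PSNR's MaxValue. HR images are center-cropped
to multiples of r before degradation. Patch pairs are aligned by
construction (LR window at (top, left), HR window at (top·r, left·r));
re-degrading an HR patch reproduces its LR patch to 1e−5 away from the
resampling boundary band.

## Synthetic phantoms

The generator emulates the image statistics the architecture separates —
large flat regions, strong edges, mild texture — without physical CT
simulation: an elliptical body at a fixed mean intensity on a smooth
background gradient, a bright bone-like ring along the body outline
(intensity step `edge_contrast`), `n_organs` interior ellipses at distinct
levels, a three-sinusoid low-frequency texture, and additive Gaussian
noise (σ = `noise_sd`, default 0.01 of full scale), all clipped to [0, 1]
and written as 16-bit PNG. Generation is pure in (spec, seed).

What phantoms do **not** model: projection/reconstruction physics (streaks,
beam hardening), anatomical texture spectra, scanner noise correlation.
Passing the pipeline on phantoms therefore demonstrates that the method
learns to invert bicubic degradation on piecewise-smooth, edge-rich
images — not clinical performance.

## Evaluation

MSE is the mean squared difference over all pixels (channels pooled);
PSNR = 10·log₁₀(MaxValue²/MSE) dB with MaxValue = 2^bits − 1. Identical
images report +∞ and are excluded from aggregate means. Evaluation
degrades each held-out HR image, super-resolves the LR copy, clips to
[0, 1], crops a `scale`-pixel border (both SR and baseline are scored on
the same interior; boundary pixels are dominated by padding and resampling
edge effects) and averages per-image PSNR. The baseline is plain bicubic
upscaling of the same LR input.

## Numerical and performance choices

- Activations are stored channels-last (B, H, W, C) so per-token layers
  and window partitioning touch contiguous memory.
- Convolutions run as one GEMM per kernel tap (9 shifted GEMMs for 3×3)
  rather than im2col: the per-tap operand is activation-sized and stays
  cache-resident, which is decisively faster on memory-bandwidth-limited
  CPUs and exact (gradients verified against finite differences).
- Softmax is computed in place with max-subtraction; relative-position
  bias and shift mask are combined into a single additive tensor per
  layer.
- The engine supports float64 end to end; gradient tests run the whole
  network in float64 against central differences.
- Adam moments are kept in float64 regardless of model dtype.

## Known limitations

- Training at the published patch size (48) is impractical on a single
  low-bandwidth core; results at the desk-scale patch size demonstrate the
  pipeline, not the published operating point.
- 2,000 updates under the exponential schedule is a short budget: the
  per-update factor 0.999 means 86% of the total learning-rate mass is
  spent by update 2,000, so the run converges to wherever the early
  updates took it. On the phantom family the resulting model is at
  statistical parity with the bicubic baseline on PSNR — the sign of the
  PSNR difference on a single held-out image varies with the dataset seed
  (a few tenths of a dB either way) — while it beats bicubic on mean
  absolute error consistently. The remaining PSNR gap concentrates in the
  squared-error tail at the strongest edges (the bone-like ring), which
  the L1 objective weights no more than any other pixel. Larger training
  patches (24 or the published 48) shift neither the loss curve plateau
  nor the held-out PSNR materially; the schedule, not the patch content,
  is binding.
- No Y-channel-only scoring; PSNR is computed on all channels (recorded in
  provenance).
- Checkpoints store the exact architecture config and refuse mismatched
  weights, but no backward-compatibility guarantees are made across
  package versions.
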