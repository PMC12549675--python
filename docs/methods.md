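# Methods

This note records the model implemented by `angioseg`, the choices made
where the design was genuinely open, and what the synthetic phantoms do and
do not establish about real angiograms.

## Problem setting

X-ray coronary angiograms show contrast-filled arteries as dark, branching,
tubular structures on a bright, noisy, slowly varying background. The
segmentation task is binary: per-pixel vessel / background. The three
difficulty axes the package is built around are complex vasculature
(bifurcations, projected crossings, thin distal branches), low contrast
(poor filling, low-dose noise), and fuzzy boundaries (motion and
partial-volume blur).

## Vesselness prior (Frangi filter)

The geometric prior is the classical multiscale Hessian line filter. At
scale σ the image is filtered with Gaussian-derivative kernels, the 2×2
Hessian H = [[Ixx, Ixy],[Ixy, Iyy]] is formed and multiplied by σ² (γ = 2
normalisation, which the filter needs for max-over-scales to be meaningful;
without it the smallest σ dominates), and its eigenvalues are ordered
|λ2| ≥ |λ1|. The response is

    V(σ) = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),  R_B = |λ1|/|λ2|,
    S = √(λ1²+λ2²),

suppressed where λ2 ≥ 0 and maximised over σ.

Choices:

* **Polarity.** The response formula above targets bright ridges (λ2 < 0).
  Angiographic vessels are dark, so the filter runs on the intensity-
  inverted frame by default; `bright_vessels=True` disables the inversion.
* **Scale schedule.** Five logarithmically spaced scales on [0.5, 5] px
  (≈2× spacing covering one decade). σ_min, σ_max, and the count are
  configurable.
* **Sensitivity constants.** β = 0.5; c = 15 interpreted on a [0, 255]
  intensity scale (inputs at other bit depths are rescaled first, since c
  depends on the grey-level range).
* **Derivative kernels.** Sampled Gaussian-derivative kernels are
  moment-corrected: the zeroth moment of each derivative kernel is forced
  to zero and the first/second moments to 1/2, so the discrete operator
  annihilates constants exactly and reproduces derivatives of polynomials
  up to degree two. Plain sampling misses these by ~1–2 % at σ near one
  pixel.
* **Ties and degeneracies.** At |λ1| = |λ2| the algebraically larger value
  is assigned to λ2; at λ2 = 0 the response is defined as 0 (flat limit).
* **Rotation covariance.** 90° rotation commutes with the pipeline to
  rounding (≤1e−12 in tests); exact bitwise equality is not attainable
  because separable filtering fixes an axis processing order.

## MVSA: multiscale vessel-structure-aware fusion

Vesselness maps are computed at three spatial scales of the frame (1×,
0.5×, 0.25×; the same σ schedule at every level — the pyramid itself
supplies scale diversity) and fused at quarter scale:

    V1 = down2(F(X)),  V2 = ReLU(N(Conv(F(X_half)))),
    V3 = ReLU(N(Conv(F(X_quarter)))),  V4 = down2(V1 + V2) + V3,
    out = ReLU(LN(Conv(CAM([V4, X′])))).

* Vessel maps stay **single-channel**; the final 3×3 convolution maps
  (C+1) → C after concatenation with the embedded features X′.
* The channel attention module (CAM) is squeeze-and-excitation: global
  average pool → bottleneck (reduction 4) → sigmoid gates.
* N on the single-channel maps is a per-map normalisation over the full
  spatial extent (`MapNorm`): channel-wise layer normalisation is
  degenerate on one channel (it returns a constant). The convolutions
  before `MapNorm` carry no bias — the normalisation is exactly invariant
  to it, which would otherwise leave a parameter with identically zero
  gradient.
* The pyramid is weight-free and depends only on the frame; it is computed
  once per forward pass and shared by both stage-1 blocks. When the prior
  is placed at deeper stages (placement ablations), the frame is first
  area-downsampled so the fused map matches that stage's resolution.
* Downsampling throughout is 2×2 area averaging; upsampling is bilinear.

## KASS: Kolmogorov–Arnold state-space block

A two-branch visual state-space unit followed by a Kolmogorov–Arnold
feed-forward:

    F1 = CAM(LN(SS2D(SiLU(DWConv(Linear(LN(x)))))))
    F2 = LocalAttention(SiLU(Linear(LN(x))))
    F3 = x + Linear(F1 ⊙ F2)
    out = FasterKAN(LN(F3)) + F3

* **SS2D.** The map is unfolded into four 1-D orders (row-major, reversed,
  column-major, reversed); each runs an input-dependent linear state-space
  recurrence h_t = exp(−Δ_t·exp(A_log))⊙h_{t−1} + Δ_t B_t x_t with readout
  y_t = C_t·h_t + D⊙x_t, where Δ, B, C are linear projections of the
  sequence (Δ through softplus). Defaults: state dimension 16, inner-width
  expansion 2, depthwise 3×3 convolution, Δ-projection rank max(d/16, 1),
  Δ initialised log-uniformly in [1e−3, 1e−1]. The recurrence runs as a
  vectorised time loop with the four directions stacked into the batch —
  a plain sequential scan; no hardware scan kernels. A naive per-element
  loop over (batch, channel, state, time) serves as the reference
  implementation in tests.
* **Branch-1 tail.** The default tail is CAM∘LN; a `branch1_tail="linear"`
  switch substitutes a plain linear layer (the two readings of the block
  description differ here, and both are runnable).
* **Local attention.** 3×3 depthwise convolution → pointwise convolution →
  sigmoid, multiplied onto the branch: a minimal neighbourhood-conditioned
  gate.
* **FasterKAN.** Each (layer-normalised) scalar feature is expanded
  through 8 reflectional-switch basis functions φ(h) = 1 − tanh²((h−g)/p)
  with centers uniform on [−2, 2] and width p = 0.33 (the grid assumes
  roughly standardised inputs), then linearly recombined to the channel
  width. The grid is fixed; only the combination weights train.
* **Ablation reduction.** Disabling the block's additions yields a vanilla
  visual state-space block: no KAN feed-forward, no local-attention gate.
* **Initialisation.** The two residual-branch output projections
  (post-gating linear and KAN combination) start at 0.1× the usual Kaiming
  scale so a freshly stacked network is near-identity and trains stably
  from scratch; zeroing them exactly makes the block the identity, which
  the tests exploit to verify the residual paths.

## CSIF: cross-stage fusion

The four encoder features E1..E4 (scales 1/4..1/32, channels C..8C) are
fused top-down:

    D4 = MPM(proj(down2(E3)) + E4)
    D3 = MIA(proj(down2(E2)), E3, proj(up2(D4)))
    D2 = MIA(proj(down2(E1)), proj(up2(D3)), E2)
    D1 = MIA(proj(up2(D2)), E1)

All cross-scale alignments are bilinear/area resize plus pointwise channel
projection. MPM adds to its input a pyramid-pooling path (bins 1, 2, 4 —
the lightest standard pyramid; configurable) and a strip-pooling path
(row and column means, a shared kernel-3 smoothing along the kept axis,
channel mixing, broadcast back), connecting distant positions along rows
and columns in one step. MIA sums its parts and applies three gating
branches — over height, width and channel — each squeezing the
complementary axes by average and standard deviation, mixing the two with
learnable weights, convolving (kernel 3) along its axis and gating through
a sigmoid; the three gated maps are averaged and passed through
conv + batch-norm + ReLU. With fusion disabled the network falls back to
identity skips (D_i = E_i).

## Network assembly

* Progressive patch embedding: two stride-2 3×3 convolutions
  (1 → C/2 → C), each with layer normalisation and GELU, then a final LN;
  C defaults to 96 (desk-scale runs use 16).
* Encoder [2,2,2,2]: stage 1 uses VSASS blocks (MVSA prior feeding a KASS
  block); stages 2–4 plain KASS. Patch merging (2×2 concatenation →
  linear 4C→2C → LN) closes stages 1–3, giving channels [C, 2C, 4C, 8C].
* Decoder [2,2,2,1], deepest (8C) to shallowest (C), mirroring the channel
  sequence; patch expanding (linear expansion + pixel rearrangement)
  doubles resolution and halves channels between stages, and the final 4×
  expansion maps C → C/4 before a 1×1 convolution and sigmoid. Each fused
  level D_i enters the decoder by elementwise addition (D4 at the
  bottleneck input, before the deepest stage).
* The head bias starts at −2: vessels are a rare foreground class, and
  starting the sigmoid near the low prior removes an initial transient in
  which the network first learns to predict background.
* Loss: BCE + (1 − soft Dice) with smoothing ε = 1 and unit weights.
* Optimisation: AdamW (lr 1e−3, β = (0.9, 0.999), ε = 1e−8, weight decay
  1e−2, no AMSGrad) with cosine annealing (T_max 50, floor 1e−5).
  Augmentation: random 90°-multiple rotations, free ±15° rotations and
  horizontal/vertical flips at p = 0.5. Epochs default to 1000 with early
  stopping on validation DSC (patience 100); desk runs override this.
* A single integer seed drives weight initialisation, data order and
  augmentation; evaluation-mode forward passes are bit-for-bit
  deterministic, and two identically seeded runs produce identical metric
  logs.

## Numerical backend

No deep-learning framework is used: the trainable blocks run on a small
reverse-mode automatic-differentiation engine over numpy arrays written
for this package (`angioseg.autodiff`), with hand-written backward passes
for the convolution and linear-recurrence kernels and composition for the
rest. All computation is float64, which keeps the scan within 1e−5 of the
sequential-loop reference and makes finite-difference gradient checks
tight. The engine is validated against central differences for every
primitive.

## Metrics

DSC, sensitivity and IoU come from exact pixel confusion counts, with the
empty-vs-empty convention DSC = IoU = Sen = 1. HD95 extracts boundary
pixels as the 8-connectivity erosion difference and takes the linearly
interpolated 95th percentile of the *pooled* bidirectional directed
distances — the common medical-imaging reading, symmetric by construction
and bounded by the full Hausdorff distance. An empty mask makes HD95
undefined; it is reported as missing and excluded from aggregation with a
warning. Summary values are unweighted means over images; mIoU is the mean
foreground IoU. Distances are in pixels unless an isotropic spacing is
given.

## Phantoms: what they emulate, and what they do not

The generator produces random recursive bifurcating trees (quadratic-
Bézier centerlines, radius decaying by 0.7 per generation, roots entering
from the frame border) rendered as dark anti-aliased swept disks on a
bright background (level ≈ 200/255) with a smooth gradient, blurred blob
shadows, Gaussian blur and additive Gaussian noise; masks are the coverage
maps binarised at 0.5. Four regimes fix the parameter ranges: `easy`
(contrast 60–110, noise 3–6), `low_contrast` (18–35, noise 6–10),
`complex` (deeper trees, two projected roots giving crossings, a
catheter-like dark curve excluded from the mask), and `fuzzy` (blur
σ 2–3.5). Everything is a pure function of the seed, so a manifest row
regenerates its files byte-for-byte.

The phantoms exercise geometry (tubes, bifurcations, crossings, thin
branches), contrast and boundary sharpness. They do **not** model cardiac
or respiratory motion, temporal sequences, projective overlap of anatomy
(spine, diaphragm, myocardium), stents or calcifications, or detector
physics. Passing the phantom-based tests therefore demonstrates that the
pipeline is correctly assembled and can learn tubular structures at desk
scale — not clinical-grade performance on real angiograms, which would
require training at full resolution on annotated clinical data.

## Verification problem sizes

The test suite and the verification script run a reduced configuration
chosen for CPU execution: embedding width C = 16, 64×64 phantoms (shape
contracts up to 256×256), batch 4, 200 optimisation steps for the
overfitting check, 20 random 32×32 images for the vesselness oracle, and
10 tube phantoms for centerline localisation. These sizes are the
package's own verification conditions; the architecture itself accepts any
input with sides divisible by 32 and the printed defaults (C = 96,
512×512) stand for full-scale use.

## Known limitations

* No pretrained-backbone initialisation: training is from scratch; an
  external weight loader is out of scope.
* CPU-bound sequential scan: fine at desk scale, not optimised for
  512×512 batches.
* The HD95 physical unit depends on pixel spacing, which angiographic
  headers often omit; results default to pixel units.
* Single-class (binary) segmentation only.
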