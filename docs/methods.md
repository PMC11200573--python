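# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limitations of `fquwf`. It states no empirical claim that the test
suite or `scripts/acceptance.py` does not itself compute.

## The model

The pipeline maps a degraded, low-resolution ultra-widefield (UWF) retinal
image to a "fundus-quality" output in two steps: a degradation-enhancement
generator `G_DE` (same input and output resolution) followed by a ×4
super-resolution generator `G_SR`. Each generator trains against its own
critic on *unpaired* data: `D_DE` compares enhanced UWF patches with
×4-bicubically-downsampled fundus patches; `D_SR` compares the upscaled
output with full-resolution fundus patches. The two critics share an
architecture but never share parameters.

### Architectures

* **`G_DE` — attention U-Net.** Encoder: `depth` convolution boxes (3×3,
  stride 2; spatial size halves, channels double). Decoder: `depth`
  transposed-convolution boxes (3×3, stride 2; spatial size doubles,
  channels halve), with skip concatenation between matching levels. After
  every encoder and decoder box sits an attention box: batch-norm →
  leaky-ReLU → operation-wise attention → leaky-ReLU. The operation-wise
  attention module applies up to six parallel channel-preserving candidate
  operations (1×1/3×3/5×5 convolutions at dilations 1–2 and 3×3 average
  pooling) and mixes them with per-sample softmax weights predicted by a
  globally pooled two-layer gate. The output head is a 3×3 convolution
  that also sees the input image itself (a level-0 skip, treating the
  input as the level-0 feature of the U-Net); its weights are
  identity-initialized on those channels (feature taps scaled by 0.01), so
  the untrained enhancer is the identity map and training learns a
  correction. Inputs not divisible by `2^depth` are zero-padded and
  cropped back.
* **`G_SR` — residual/pixel-shuffle upscaler.** Feature extractor (3×3
  conv + PReLU), `n_residual_blocks` residual blocks (conv+BN → PReLU →
  conv+BN → sum), a conv+BN with a global skip from the extractor, then
  log2(scale) stages of 3×3 convolution + ×2 pixel shuffle. The
  channel-calibration 3×3 convolution reduces to 3 channels; it sees the
  learned features concatenated with a fixed bilinear ×scale upsampling of
  the input and is identity-initialized on those channels, so the
  untrained upscaler reproduces plain interpolation and training learns
  residual detail. Zeroing the calibration convolution still yields the
  zero image — the interpolation stream passes through the same
  convolution.
* **Critic.** 3×3 conv + leaky-ReLU, then a ladder of conv+BN+leaky-ReLU
  blocks with channels doubling up to 8× the base width (strides
  alternating 1/2; a shorter 4-block ladder in `tiny_mode`), global
  average pooling, two dense layers, and a sigmoid to one score per image
  in (0, 1). Inputs below the receptive-field minimum raise an error.

The residual-from-identity initializations are a desk-scale design: a
from-scratch upscaler cannot reach useful reconstruction in the few
hundred iterations this package trains for, and an enhancer that starts at
the identity preserves the fine detail (small bright lesions) that the
study's evaluation hinges on. Both initializations vanish asymptotically —
they bias where training starts, not what the losses demand.

### Losses

All adversarial terms are the standard non-saturating forms with critic
probabilities clamped to `[1e−7, 1 − 1e−7]`:

    d_loss = −E[log D(real)] − E[log(1 − D(fake))]
    g_loss = −E[log D(fake)]

(The composite objectives as sometimes printed in the GAN literature with
"1 − log D" are not bounded below; this package uses the canonical form.)

* **Identity (λ_I = 0.5).** `E‖G_DE(z) − z‖₁` with `z` drawn from the
  *source* (UWF) domain: the enhancer must not restyle what it is given.
* **Weight anchor (λ_R = 0.1).** Mean squared distance of the currently
  trainable enhancer parameters from their pretrained snapshot (frozen
  parameters are excluded — they cannot drift).
* **One-way cycle (λ_C = 0.5).** `E‖G_SR(x↓4) − x‖₁` on fundus images:
  downsample by the pipeline's ×4 factor, super-resolve, compare. No
  reverse generator is learned. Images not divisible by 4 are cropped.
* **Composites.** Stage DE minimizes `g_loss + λ_I·identity + λ_R·anchor`;
  stage SR minimizes `g_loss + λ_C·cycle`; macular fine-tuning minimizes
  their sum on macular patches. L1 is used for both unlabeled norms,
  following cycle-consistency convention.

### Training schedule

Four stages, all AdamW (β = (0.9, 0.999), ε = 1e−8, decoupled weight decay
1e−2), learning rate halved every `lr_halving_period` iterations,
rotation/flip patch augmentation, alternating critic/generator updates:

1. **Pretraining** (nothing frozen): supervised L1 reconstruction of
   clean-at-working-resolution targets from synthetically degraded
   phantoms, standing in for initialization on an external retinal
   restoration corpus. The resulting parameters become the anchor.
2. **Stage DE** (encoder frozen; decoder and attention update):
   adversarial adaptation against `D_DE`.
3. **Stage SR** (all of `G_DE` frozen, run in eval mode so that not even
   batch-norm statistics move): `G_SR` trains from scratch against `D_SR`
   plus the cycle term.
4. **Macular fine-tuning** (nothing frozen): joint optimization of both
   generators on patches whose centers lie inside the macular region
   (from the dataset manifest for phantoms; a central disk of radius
   0.25·min(H, W) for images without a known macula).

Reference hyperparameters (batch 16, 128-pixel patches, lr 1e−3) are the
defaults of `StageConfig`. The tested desk-scale profile
(`StageConfig.tiny`) uses batch 4 and 64-pixel fundus patches (16-pixel
UWF patches — the two domains differ by the ×4 factor) with 500 iterations
per stage (200 for fine-tuning), and deviates from the reference
optimization in three deliberate ways:

* **Critic initialization.** Each adversarial stage first trains its
  critic alone for 200 steps at lr 1e−3 before any adversarial generator
  step. At batch 4 a critic that starts cold never provides a meaningful
  signal inside a 500-iteration window.
* **Update ratio.** After initialization the critic is held essentially
  fixed (`critic_interval` larger than the run). In a balanced 1:1
  schedule at this scale the critic always outruns the generator, and its
  gradient then degrades the generator's output fidelity without limit.
* **Generator rates.** 1e−5 (DE), 1e−3 (SR, training from scratch),
  2.5e−5 (fine-tuning). Gradient noise at batch 4 is several times that of
  the reference batch; the adversarial stages adapt a network that is
  already good, and large steps destroy more than they adapt.

Batch-norm statistics are (re-)estimated only during pretraining, on whole
images. The adaptation stages and fine-tuning run the generators with
frozen statistics: re-estimating them on small crops or on macular-only
patches (a biased sample of the image) measurably skews full-image
inference.

Checkpoints (parameters, optimizer moments, RNG state, anchor) are written
per stage as a compressed array archive plus a JSON sidecar; save → load →
step reproduces step-without-save bit for bit, and later stages raise a
staging error when the checkpoints of earlier ones are absent.

## Synthetic phantoms

`generate_phantom` renders, deterministically from (parameters, seed): a
radial-gradient orange/red background with low-frequency texture; a bright
optic disc ellipse; `n_vessels` dark curvilinear vessels grown from the
disc by a second-order random walk with Gaussian cross-section stamping; a
darker macular disc; and `n_drusen` bright deposits (disks of radius 1–3
px, +0.2 to +0.4 brightness) confined to a macular radius of size/6, whose
union is kept as a binary mask. Defaults: 96-pixel side, 7 vessels, 5
drusen, noise 0.01.

UWF-like counterparts apply a degradation chain and then seeded Gaussian
pixel noise. The default synthesis chain is Gaussian blur σ = 3, uneven
illumination γ = 0.75, JPEG rate 0.5, bicubic ×0.25. The *operator*
defaults of `DegradationSpec` remain the severe suite (σ = 7, γ = 0.75,
rate 0.25, scale 0.25) used for robustness experiments; for ~100-pixel
phantom synthesis that suite is proportionally far harsher than the
optics of a real UWF capture (whose side runs to thousands of pixels) and
erases the macular deposits outright, contradicting the clinical premise
that macular detail is degraded but recoverable. Blur support is read as
kernel *support* σ×σ (rounded up to odd) with standard deviation σ/3 — the
printed size is honored while the kernel stays a decaying Gaussian.
"Uneven illumination" is realized as a radial cosine ramp of the gamma
exponent from 1 at the center to γ at the corners, which is analytically
testable at both anchors. JPEG "rate" maps to codec quality 100·rate.

`build_unpaired_dataset` writes n clean and n UWF-like images whose domains
are unpaired by permuting phantom seeds between them (the permutation is
never the identity for n ≥ 2); the manifest records files, seeds, the
hidden pairing, macula centers, and the chain, and ground-truth drusen
masks are stored beside the clean images. Training code never reads the
pairing; evaluation oracles do. The default corpus is 40 images per domain
— small enough to synthesize in seconds, large enough that the critics
cannot simply memorize scene identity, which at a handful of images per
domain replaces the intended domain signal entirely.

What the phantoms do **not** model: peripheral-field geometry,
eyelash/eyelid artifacts, real vessel branching statistics, pathology
other than drusen-like deposits, and scanner-specific noise. A passing
test suite therefore demonstrates that the method's machinery behaves as
specified under controlled conditions, not that it reaches clinical
quality on real UWF data.

## Evaluation

* **Sharpness** is the re-blur gradient-ratio estimate: blur the luminance
  with a fixed 9-tap averaging filter, compare neighboring-pixel variation
  before and after along each axis, return the normalized maximum ratio in
  [0, 1]. Re-blurring an already blurry image changes little, so lower
  values mean sharper images; a constant image returns 1.0 by convention.
  The exact formulation of this no-reference score varies across the
  literature; this deterministic variant is the package's fixed choice.
* **IoU / mAP.** Intersection-over-union of binary masks (1.0 when both
  are empty), and mAP defined literally as the mean per-image IoU in
  percent — not a detection-style average precision over thresholds.
* **Drusen detection** (`detect_bright_blobs`) runs Laplacian-of-Gaussian
  blob detection on background-subtracted luminance at the expected lesion
  scales (radii ~1–3 px at a reference macular radius of 16, scaled
  proportionally) and rasterizes accepted blobs as disks. Scale
  selectivity keeps the detector on compact deposits rather than on the
  bright sidebands that background subtraction creates along sharp
  vessels. In the end-to-end experiment the detector runs on the enhanced
  output at its native (×4) resolution and on the raw degraded input at
  *its* native resolution (detections block-upscaled to ground-truth
  scale) — mirroring how raw versus enhanced images would each be
  annotated directly.
* **Group statistics.** One-way fixed-effects ANOVA from explicit sums of
  squares (identical group means give F = 0, p = 1; zero within-group
  variance with distinct means gives the F = ∞, p = 0 sentinel), and
  Bonferroni-adjusted pairwise two-sided Welch t-tests,
  `p_adj = min(1, m·p)`.
* **LPIPS / FID** are adapters over the reference implementations and
  return `None` when those optional backends are not installed — never a
  substitute number.
* **PSNR** against the hidden paired clean source exists for phantom
  oracles only (both sides compared at the enhancer's working resolution,
  i.e. against the ×4-downsampled clean image); it is deliberately not
  part of the headline report, which assumes unpaired data.

## Numerical choices

* All image math is float64 in [0, 1]; 8-bit (or 16-bit) encodings exist
  only at the file boundary. Generator outputs are clipped at inference
  only.
* Bicubic resampling uses half-pixel centers (antialiased when
  downsampling); resampling at scale 1 is the exact identity.
* The autograd engine is a plain reverse-mode tape over NumPy arrays;
  convolutions use offset-sliced im2col/col2im, and gradients were
  verified against central differences in the test suite.
* Seed fan-out: one global seed is mixed with a stable label hash per
  component (`derive_seed`), so partial re-runs reproduce the full run
  component by component.

## Known limitations

* The desk-scale adversarial schedule (initialized, then nearly fixed
  critics) demonstrates the training dynamics the staged scheme is built
  around, but it is not the balanced alternating optimization a full-scale
  run would use; the balanced schedule is available via `StageConfig`.
* Stage DE's adaptation margin is small in the phantom world: supervised
  pretraining on the same synthesis chain already solves most of the
  restoration task, so the unpaired adaptation has little left to close.
  With a genuinely external pretraining corpus the stage would carry more
  of the burden.
* The drusen experiment scores a simple blob detector, not clinical
  annotators; it measures lesion *visibility to a fixed algorithm*, which
  is the automatable proxy for the visibility-to-annotators comparison it
  imitates.
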