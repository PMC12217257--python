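# Methods

## Overview

`histodiff` implements a two-phase approach to breast-cancer detection in
histology patches. Phase one is a **conditional denoising diffusion
probabilistic model (DDPM)** that performs semantic segmentation of tissue
regions: instead of generating images, the diffusion chain operates on an
encoded label mask, conditioned at every step on the RGB patch. Phase two
is a **multimodal fusion classifier**: the original image, the predicted
mask and the predicted noise map are each tokenised by a convolutional
backbone and fused — by concatenation, self-attention, cross-attention, or
a transformer decoder — into a binary normal/cancer decision.

## Segmentation model

A ground-truth mask with K tissue classes (the five-class legend is
Other / Tumor / Stroma / Inflammation / Necrosis) is one-hot encoded over
K channels and rescaled to {−1, +1}. The forward process corrupts this
encoding x₀ through the Markov chain

    x_t = √(1−β_t) x_{t−1} + √β_t ε,   ε ~ N(0, I),  t = 1..T,

with a linear variance schedule β₁..β_T. With α_t = 1 − β_t and
ᾱ_t = Π_{s≤t} α_s the marginal is available in closed form,

    x_t = √ᾱ_t x₀ + √(1−ᾱ_t) ε,

which training uses directly: each step draws a uniform t, corrupts the
encoded mask, and regresses the U-Net's prediction ε̂(x_t, y, t) onto the
drawn noise under the batch-mean squared-L2 loss
L = (1/m) Σᵢ ‖εᵢ − ε̂ᵢ‖². Conditioning on the image y is by channel
concatenation: the network input is the 3+K-channel stack [y, x_t].

The denoiser is a U-Net whose levels halve the spatial size on the way
down and double it on the way up, built from residual blocks
(GroupNorm → SiLU → conv, with a projected sinusoidal time embedding
added between the two convolutions) plus spatial self-attention blocks at
configurable levels (default: the deepest level only). Channel widths
double per level from `base_channels`.

At test time the mask is unknown, so segmentation runs the reverse chain
from pure noise x_T ~ N(0, I). Each reverse step applies the posterior
mean

    μ = (x_t − (β_t/√(1−ᾱ_t)) ε̂) / √α_t,

plus σ_t·z noise with σ_t² = β_t (`fixed_beta` mode) or σ_t = 0 (`zero`
mode); the final step always returns the mean. The decoded prediction is
the per-pixel argmax over the K channels of the final x₀ estimate (ties
go to the lowest class index). The ε̂ of the final reverse step is kept
as the third classification modality (configurable: mean over the last N
steps, or a fixed intermediate step).

### Numerical choices in the sampler

* **Implied-x₀ clipping** (`clip_denoised`, default on): each reverse
  step clamps the implied x₀ = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t to the encoding
  range [−1, 1] and re-derives the equivalent ε̂ before the posterior
  update. Without it, early prediction errors inflate the trajectory far
  outside the range the denoiser was trained on and segmentation quality
  collapses (on the toy task, foreground IoU ≈ 0.26 without clipping
  versus ≈ 0.9 with it).
* **Reduced-step inference**: a run with S < T steps visits an evenly
  spaced decreasing subsequence of timesteps ending at 1 and rescales
  the schedule over the visited steps (β′ᵢ = 1 − ᾱ(tᵢ)/ᾱ(tᵢ₋₁)), so the
  marginals match at every visited step; with S = T this is bit-identical
  to the full sampler. The denoiser is conditioned on the original
  timestep indices. S = 1 is single-shot inversion of the closed form.
* **Schedule endpoints at reduced T**: the linear schedule defaults to
  β ∈ [1e-4, 0.02] at T = 1000, for which ᾱ_T ≈ 4·10⁻⁵. A shortened toy
  schedule must preserve ᾱ_T ≈ 0 — otherwise the reverse chain's
  starting point (pure noise) is outside the training distribution — so
  the toy profile uses β ∈ [1e-4, 0.3] at T = 50 (ᾱ_T ≈ 2·10⁻⁴).
* The toy profile samples with the `zero` variance mode: at 16×16 the
  β-sized noise injections are large relative to the signal and
  measurably degrade masks (foreground IoU ≈ 0.5 vs ≈ 0.76 at 10 steps).

## Detection model

The frozen segmenter supplies, for each patch, a mask and a noise map.
Three aligned H×W×3 views are built: the image (clipped to [0,1]), the
mask rendered through a fixed palette (class 0 → black, 1 → red,
2 → green, 3 → blue, 4 → yellow, ...), and the noise map (first three
channels, cycled if K < 3, each channel standardised to mean 0 / sd 1;
constant channels map to 0). A convolutional backbone turns each view
into a token sequence: the final feature grid is flattened and linearly
projected to `embed_dim`. The default backbone is a small strided
CNN; an MBConv backbone (inverted bottleneck blocks with depthwise
convolutions and SiLU/swish activation, the building block of
compound-scaled efficient CNNs) is available, and backbones may be
shared across modalities (default) or separate. Pre-trained weights are
not required anywhere.

Fusion modes over the token bundles:

* `concat` — mean-pool each modality's tokens, concatenate the pooled
  vectors (output dimension m·D for m modalities);
* `self_attention` — joint multi-head self-attention over all tokens,
  then mean-pool;
* `cross_attention` — the query modality's tokens attend over the
  concatenated remaining tokens, then mean-pool;
* `transformer_decoder` — full pre-norm decoder layers (self-attention
  on the query stream, cross-attention to the memory, position-wise
  feed-forward, residuals + layer norm), then mean-pool.

Image tokens serve as decoder queries by default (configurable); all
sequences receive sinusoidal positional encodings (optional) and a
learned per-modality embedding. A linear head with softmax yields the
cancer probability; the decision threshold is 0.5. Training uses
cross-entropy with AdamW on cached segmentations — no gradient reaches
the segmenter, which is architecturally guaranteed by precomputing the
masks before detector training.

The ablation harness trains the same data through six scenarios
(image-only baseline, three-modality concatenation, self-attention,
cross-attention, and the transformer decoder with two and with three
modalities) and reports accuracy, a 95% binomial confidence interval and
PR-AUC per scenario.

## Evaluation metrics

Segmentation is scored per class one-vs-rest at pixel level from pooled
dataset-level confusion counts: IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN). A class absent from both prediction and ground
truth scores 1.0 (the 0/0 convention). Detection reports accuracy with a
normal-approximation binomial confidence interval (Wilson available via
a flag) and PR-AUC with step-wise interpolation (average precision).
"Foreground IoU" is the mean IoU over classes 1..K−1.

## Synthetic data

The fixture generator emulates stained tissue patches at arbitrary
scale: class 0 is the background; for each foreground class, 0–2 random
ellipses (rotation, semi-axes and centres drawn uniformly) are stamped
in class order, later classes overwriting earlier ones. The image is
the per-pixel class mean colour (an H&E-inspired palette) plus Gaussian
texture noise, clipped to [0,1]; the mask is the exact stamped class
map. Detection labels derive from tumor-class presence, and the
detection generator realises an exact cancer count of
round(n·cancer_fraction), redrawing a patch if a forced tumor blob was
fully overwritten. A texture-only mode gives all classes the same mean
colour and distinguishes them by noise standard deviation alone, which
moves the class signal out of the colour channel (used to show that
mask-aware fusion can beat an image-only classifier).

What the generator does **not** emulate: realistic H&E stain variation,
nuclear morphology, spatial correlation of texture, scanner artefacts,
class co-occurrence statistics, or whole-slide context. Passing the
recovery tests therefore demonstrates that the implementation learns and
samples correctly end to end, not that it reaches any particular
performance on real histopathology.

## Default parameters

Reference profile: AdamW, base learning rate 1e-4, 5000
linear-warmup steps, 2·10⁵ training steps, batch 16, 128×128 patches,
K = 5, T = 1000 linear schedule with β ∈ [1e-4, 0.02]; weight decay
0.01 (the AdamW convention; decoupled decay strength is otherwise
unspecified).

Toy profile (what the test suite and the acceptance script run):
16×16 patches, K = 3, 200 segmentation patches (140/30/30
train/val/test), T = 50 with β ∈ [1e-4, 0.3], U-Net with
base_channels 16 / depth 2 / attention at the bottleneck, learning rate
2e-3 with 100 warmup steps, 3200 training steps, batch 16; inference
with 25 strided steps, zero-variance mode; detection on 400 patches
(cancer fraction 0.5, 280/120 split), shared small-CNN backbone,
embed_dim 32, 4 heads, 1 decoder layer, 25 epochs at lr 1e-3 with
random dihedral (flip/rot90) augmentation. Segmenter training uses
global-norm gradient clipping (1.0), cosine learning-rate decay after
warmup, and an exponential moving average of the weights (decay 0.995)
as the returned model; without these, quality varies strongly with the
training seed. The
determinism check reruns the same pipeline at reduced counts (40
training steps, 24/40 patches, 3 epochs), which exercises identical code
paths. These sizes are the package's chosen tiny-scale study
conditions; they fit in CPU-minutes.

## Known limitations

* One sampling trajectory per image (an ensemble hook exists but is off
  by default), so segmentations vary with the sampling seed.
* The numpy-based network layer is single-threaded and float64; it is
  sized for small-patch experiments, not for 128×128 × T=1000 training,
  which requires a GPU-scale framework.
* The respaced strided sampler conditions the denoiser on original
  timesteps while stepping the sub-schedule; at very small S this
  approximation (shared by standard step-reduction practice) coarsens
  boundaries.
* Per-class IoU/Dice are aggregated at dataset level (pooled counts);
  per-image macro-averaging would give different numbers on imbalanced
  data.
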