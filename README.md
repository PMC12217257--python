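# histodiff

Conditional-diffusion tissue segmentation and multimodal fusion
detection for breast-cancer histology patches.

## The problem

Pixel-accurate tissue maps (tumor, stroma, inflammation, necrosis, other)
are expensive to annotate, yet they carry structure that plain
patch-level classifiers miss. `histodiff` implements a two-phase method:

1. **Segmentation by conditional DDPM.** A denoising diffusion
   probabilistic model operates on a one-hot encoded label mask x₀
   (channels scaled to {−1, +1}). The forward process corrupts it,
   x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε with ᾱ_t = Π_{s≤t}(1−β_s), and a U-Net
   ε̂(x_t, y, t) — conditioned on the histology patch y by channel
   concatenation, with sinusoidal time embeddings and attention blocks —
   is trained to predict the noise by minimising
   L = (1/m) Σᵢ ‖εᵢ − ε̂ᵢ‖². At test time the reverse chain turns pure
   noise into a mask for an unseen patch, and the predicted-noise map
   falls out as a by-product.
2. **Detection by multimodal fusion.** The original image, the rendered
   predicted mask, and the predicted noise are each tokenised by a
   convolutional backbone (small CNN or MBConv); a transformer decoder
   (or, for ablation, simple concatenation / self-attention /
   cross-attention) fuses the token bundles into a binary normal/cancer
   score. The segmenter stays frozen during detector training.

Evaluation uses per-class IoU and Dice for segmentation, and accuracy
with a 95% binomial confidence interval plus PR-AUC for detection.

All networks run on a compact numpy reverse-mode autodiff layer included
in the package (`histodiff._nn`), so everything trains on a single CPU at
small patch sizes. A seeded synthetic-fixture generator provides
histology-like patches with exact ground truth, making the whole pipeline
testable without downloads. See `docs/methods.md` for model details and
defaults.

## Worked example

```python
import numpy as np
from histodiff import (FixtureSpec, generate_segmentation_dataset,
                       linear_schedule, DenoiserConfig, build_denoiser,
                       TrainSettings, train_segmenter, SamplerConfig,
                       segment, mean_foreground_iou)

spec = FixtureSpec(size=16, K=3, n=200, seed=42)        # toy-scale patches
ds = generate_segmentation_dataset(spec)
schedule = linear_schedule(50, 1e-4, 0.3)               # T=50, hot endpoint
net = build_denoiser(DenoiserConfig(K=3, base_channels=16, depth=2), 7)
net, trace = train_segmenter(
    ds.train, net, schedule,
    TrainSettings(lr=2e-3, warmup_steps=100, train_steps=3200, batch_size=16),
    rng_seed=0)
cfg = SamplerConfig(schedule=schedule, inference_steps=25, variance_mode="zero")
preds = [segment(net, p.image, cfg, rng_seed=99).mask for p in ds.test]
iou = mean_foreground_iou(preds, [p.mask for p in ds.test], K=3)
print(f"final loss {trace[-1]:.1f}, held-out foreground IoU {iou:.3f}")
```

This trains the toy-profile segmenter (a few CPU-minutes) and prints

```
final loss 60.0, held-out foreground IoU 0.947
```

the mean IoU over the two foreground tissue classes on 30 held-out
patches: ~95% overlap between predicted and true regions, from pure
noise, guided only by the image. The equivalent staged run via the CLI:

```bash
histodiff run --profile toy --seed 0 --out runs/toy
histodiff ablate-fusion --seed 0 --out runs/toy/fusion_ablation.csv
```

which writes `segmentation_metrics.csv` (per-class IoU/Dice),
`detection_metrics.csv` (accuracy, 95% CI, PR-AUC of the three-modality
transformer-decoder detector) and a six-scenario fusion-ablation table.

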