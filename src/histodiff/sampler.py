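"""Training and inference procedures for the diffusion segmenter.

Training: for each batch, draw a uniform step t, a Gaussian noise field
ε, corrupt the encoded ground-truth mask with the closed-form forward
jump, and regress the U-Net's prediction onto ε (conditioned on the RGB
image) under the batch-mean squared-L2 loss, with AdamW and linear
warmup.

Inference: segmentation starts from pure noise and walks the reverse
chain. Each reverse step applies the posterior mean

    μ = (x_t − (β_t/sqrt(1−ᾱ_t))·ε̂) / sqrt(α_t)

plus σ_t·z noise (σ_t² = β_t, or 0 in the deterministic mode); the final
step returns the mean exactly. Reduced-step inference visits an evenly
spaced subsequence of timesteps and rescales the schedule over the
visited steps (β'_i = 1 − ᾱ(t_i)/ᾱ(t_{i−1})), which leaves the full-step
sampler bit-identical to the unstrided one. The ε̂ map of the final
reverse step is kept as the third classification modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import AdamW, Tensor
from .diffusion import NoiseSchedule, invert_q_sample
from .mask_codec import LabelMask, decode_mask, encode_mask
from .denoiser import UNetDenoiser

logger = logging.getLogger("histodiff")

__all__ = [
    "SamplerConfig",
    "TrainSettings",
    "SegmentationResult",
    "stride_timesteps",
    "posterior_step",
    "train_segmenter",
    "segment",
    "segment_batch",
]


@dataclass(frozen=True)
class SegmentationResult:
    """Predicted mask plus the predicted-noise map used for detection."""

    mask: LabelMask
    noise_map: np.ndarray
    steps_used: int
    seed: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.noise_map)):
            raise ValueError("noise_map contains non-finite values")
        if self.steps_used < 1:
            raise ValueError("steps_used must be >= 1")


@dataclass
class SamplerConfig:
    """Reverse-diffusion settings.

    ``noise_modality_rule`` selects which ε̂ becomes the classification
    noise map: "final" (the t=1 prediction, default), "mean_last_n", or
    "fixed_t" (the prediction at ``noise_fixed_t``).
    """

    schedule: NoiseSchedule
    inference_steps: int | None = None
    variance_mode: str = "fixed_beta"
    clip_denoised: bool = True
    noise_modality_rule: str = "final"
    noise_last_n: int = 5
    noise_fixed_t: int | None = None

    def __post_init__(self):
        if self.inference_steps is None:
            self.inference_steps = self.schedule.T
        if not (1 <= self.inference_steps <= self.schedule.T):
            raise ValueError(
                f"inference_steps={self.inference_steps} outside 1..T={self.schedule.T}")
        if self.variance_mode not in ("fixed_beta", "zero"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.noise_modality_rule not in ("final", "mean_last_n", "fixed_t"):
            raise ValueError(f"unknown noise_modality_rule {self.noise_modality_rule!r}")
        if self.noise_modality_rule == "fixed_t" and self.noise_fixed_t is None:
            raise ValueError("noise_fixed_t required for the fixed_t rule")


@dataclass
class TrainSettings:
    """Optimiser settings; defaults follow the reference training recipe
    (AdamW, base learning rate 1e-4, 5000 warmup steps, 2e5 training
    steps, batch size 16)."""

    lr: float = 1e-4
    warmup_steps: int = 5000
    train_steps: int = 200_000
    batch_size: int = 16
    weight_decay: float = 0.01
    grad_clip: float | None = 1.0
    lr_decay: str = "cosine"  # "cosine" after warmup, or "none"
    ema_decay: float | None = 0.995  # weight EMA used for the returned model


def stride_timesteps(T: int, inference_steps: int) -> np.ndarray:
    """Evenly spaced decreasing timestep subsequence ending at 1.

    ``inference_steps == 1`` returns [T] (single-shot inversion);
    otherwise the sequence has exactly ``inference_steps`` strictly
    decreasing entries from T down to 1.
    """
    if not (1 <= inference_steps <= T):
        raise ValueError(f"inference_steps={inference_steps} outside 1..T={T}")
    if inference_steps == 1:
        return np.array([T], dtype=np.int64)
    ts = np.floor(np.linspace(T, 1, inference_steps) + 0.5).astype(np.int64)
    # rounding can collapse neighbours when the spacing is ~1; repair while
    # keeping the endpoints fixed
    for i in range(1, len(ts)):
        if ts[i] >= ts[i - 1]:
            ts[i] = ts[i - 1] - 1
    if ts[-1] < 1:
        raise ValueError("cannot build a strictly decreasing subsequence")
    return ts


def posterior_step(x_t, epsilon_hat, t: int, schedule: NoiseSchedule,
                   variance_mode: str = "fixed_beta",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """One reverse step x_t → x_{t−1} given the predicted noise.

    Works on maps of any shape. For t > 1 the fixed-β variance mode adds
    sqrt(β_t)·z with z ~ N(0, I); the zero mode and the final step (t=1)
    return the posterior mean exactly.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    x_t = np.asarray(x_t, dtype=np.float64)
    epsilon_hat = np.asarray(epsilon_hat, dtype=np.float64)
    if x_t.shape != epsilon_hat.shape:
        raise ValueError(f"shape mismatch: x_t {x_t.shape} vs epsilon_hat {epsilon_hat.shape}")
    beta = schedule.beta_at(t)
    alpha = schedule.alpha_at(t)
    abar = schedule.alpha_bar_at(t)
    mean = (x_t - (beta / np.sqrt(1.0 - abar)) * epsilon_hat) / np.sqrt(alpha)
    if t == 1 or variance_mode == "zero":
        return mean
    if rng is None:
        raise ValueError("fixed_beta variance mode needs an rng for t > 1")
    return mean + np.sqrt(beta) * rng.standard_normal(x_t.shape)


def _respaced_schedule(schedule: NoiseSchedule, ts_desc: np.ndarray) -> NoiseSchedule:
    """Schedule over the visited steps with matching marginals ᾱ."""
    abars = schedule.alpha_bar[ts_desc[::-1] - 1]  # increasing t order
    prev = np.concatenate([[1.0], abars[:-1]])
    betas = 1.0 - abars / prev
    return NoiseSchedule(T=len(betas), beta=betas, family="respaced")


def train_segmenter(data, denoiser: UNetDenoiser, schedule: NoiseSchedule,
                    settings: TrainSettings | None = None,
                    rng_seed: int = 0, callback=None):
    """Fit the denoiser on image/mask pairs; returns (handle, loss trace)."""
    settings = settings or TrainSettings()
    patches = list(data)
    if not patches:
        raise ValueError("empty training set")
    for i, p in enumerate(patches):
        if p.mask is None:
            raise ValueError(f"patch {i} has no ground-truth mask; training requires masks")
    logger.info("train_segmenter: %d patches, %d steps, seed=%d",
                len(patches), settings.train_steps, rng_seed)
    rng = np.random.default_rng(int(rng_seed))
    x0 = np.stack([encode_mask(p.mask).values.transpose(2, 0, 1) for p in patches])
    cond = np.stack([p.image.transpose(2, 0, 1) for p in patches])
    n = len(patches)
    opt = AdamW(denoiser.parameters(), lr=settings.lr,
                weight_decay=settings.weight_decay, warmup_steps=settings.warmup_steps,
                total_steps=settings.train_steps if settings.lr_decay == "cosine" else None,
                grad_clip=settings.grad_clip)
    ema = ([p.data.copy() for p in denoiser.parameters()]
           if settings.ema_decay is not None and settings.lr > 0.0 else None)
    trace = []
    for step in range(settings.train_steps):
        idx = rng.integers(0, n, size=min(settings.batch_size, n))
        t = rng.integers(1, schedule.T + 1, size=len(idx))
        eps = rng.standard_normal(x0[idx].shape)
        abar = schedule.alpha_bar[t - 1][:, None, None, None]
        x_t = np.sqrt(abar) * x0[idx] + np.sqrt(1.0 - abar) * eps
        pred = denoiser.forward(Tensor(x_t), Tensor(cond[idx]), t)
        diff = pred - Tensor(eps)
        loss = (diff * diff).sum(axis=(1, 2, 3)).mean()
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss {value} at training step {step}; aborting "
                f"(lr={opt.current_lr():.2e}, t range {t.min()}..{t.max()})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if ema is not None:
            d = settings.ema_decay
            for shadow, p in zip(ema, denoiser.parameters()):
                shadow *= d
                shadow += (1.0 - d) * p.data
        trace.append(value)
        if callback is not None:
            callback(step, value)
    if ema is not None:
        for shadow, p in zip(ema, denoiser.parameters()):
            p.data = shadow.copy()
    return denoiser, trace


def segment_batch(handle: UNetDenoiser, images, config: SamplerConfig,
                  rng_seed: int) -> list[SegmentationResult]:
    """Reverse-diffuse a batch of images in lockstep (one trajectory each)."""
    schedule = config.schedule
    K = handle.config.K
    imgs = np.stack([np.asarray(im, dtype=np.float64).transpose(2, 0, 1) for im in images])
    B, _, H, W = imgs.shape
    if imgs.shape[1] != 3:
        raise ValueError("images must be H×W×3")
    logger.info("segment: %d image(s), %d steps, seed=%d", B, config.inference_steps, rng_seed)
    rng = np.random.default_rng(int(rng_seed))
    x = rng.standard_normal((B, K, H, W))
    ts = stride_timesteps(schedule.T, config.inference_steps)
    if config.inference_steps == 1:
        eps_hat = handle.predict(x, imgs, np.full(B, schedule.T))
        x = np.stack([invert_q_sample(x[i], eps_hat[i], schedule.T, schedule)
                      for i in range(B)])
        noise_map = eps_hat
    else:
        sub = _respaced_schedule(schedule, ts)
        collected, noise_map = [], None
        for i, t_orig in enumerate(ts):
            sub_t = len(ts) - i  # respaced index, T'..1
            eps_hat = handle.predict(x, imgs, np.full(B, t_orig))
            if config.noise_modality_rule == "fixed_t" and t_orig == config.noise_fixed_t:
                noise_map = eps_hat
            if config.noise_modality_rule == "mean_last_n" and i >= len(ts) - config.noise_last_n:
                collected.append(eps_hat)
            eps_step = eps_hat
            if config.clip_denoised:
                # clamp the implied x0 to the encoding range [-1, 1] and
                # re-express it as an equivalent noise estimate; this keeps
                # the trajectory on the scale the denoiser was trained on
                abar = sub.alpha_bar_at(sub_t)
                x0_hat = np.clip((x - np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(abar),
                                 -1.0, 1.0)
                eps_step = (x - np.sqrt(abar) * x0_hat) / np.sqrt(1.0 - abar)
            x = posterior_step(x, eps_step, sub_t, sub, config.variance_mode, rng)
        if config.noise_modality_rule == "final" or noise_map is None and not collected:
            noise_map = eps_hat
        elif collected:
            noise_map = np.mean(collected, axis=0)
    results = []
    for i in range(B):
        mask = decode_mask(x[i].transpose(1, 2, 0))
        results.append(SegmentationResult(
            mask=mask, noise_map=noise_map[i].transpose(1, 2, 0),
            steps_used=int(config.inference_steps), seed=int(rng_seed)))
    return results


def segment(handle: UNetDenoiser, image: np.ndarray, config: SamplerConfig,
            rng_seed: int) -> SegmentationResult:
    """Segment one RGB image from pure noise; fixed seed ⇒ fixed output."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"image must be H×W×3, got shape {image.shape}")
    return segment_batch(handle, [image], config, rng_seed)[0]


def segment_ensemble(handle: UNetDenoiser, image: np.ndarray, config: SamplerConfig,
                     rng_seed: int, n_realizations: int = 1) -> SegmentationResult:
    """Ensemble hook: majority-vote over several sampling trajectories.

    The default single realization reduces to :func:`segment`. With more,
    per-pixel labels are decided by vote (ties to the lowest class) and
    the noise maps are averaged."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if n_realizations == 1:
        return segment(handle, image, config, rng_seed)
    runs = [segment(handle, image, config, rng_seed + i) for i in range(n_realizations)]
    K = handle.config.K
    votes = np.zeros(runs[0].mask.shape + (K,), dtype=np.int64)
    rows, cols = np.indices(runs[0].mask.shape)
    for r in runs:
        votes[rows, cols, r.mask.labels] += 1
    mask = LabelMask(labels=np.argmax(votes, axis=2), K=K)
    noise = np.mean([r.noise_map for r in runs], axis=0)
    return SegmentationResult(mask=mask, noise_map=noise,
                              steps_used=runs[0].steps_used, seed=int(rng_seed))
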