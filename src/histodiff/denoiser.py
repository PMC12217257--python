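"""Conditional noise-prediction network.

A U-Net over the channel concatenation of the RGB condition image and
the noisy encoded mask, predicting the Gaussian noise that produced the
noisy mask. Each resolution level halves the spatial size on the way
down and doubles it on the way up; skip connections join matching
levels. Every residual block receives a projection of the sinusoidal
time embedding, so the network knows the corruption level it is
denoising. At configurable levels the residual block is followed by a
spatial self-attention block (default: the deepest level only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Tensor
from .diffusion import NoiseSchedule

__all__ = [
    "DenoiserConfig",
    "DenoiserOutput",
    "sinusoidal_time_embedding",
    "build_denoiser",
    "denoise",
    "UNetDenoiser",
    "save_checkpoint",
    "load_checkpoint",
]


def sinusoidal_time_embedding(t, dim: int) -> np.ndarray:
    """Sinusoidal position encoding of time step(s) t.

    The first dim/2 components are sin(t/ω_j), the second half
    cos(t/ω_j), with frequencies ω_j geometrically spaced from 1 to
    10000. Accepts a scalar (returns shape (dim,)) or an array of steps
    (returns (len(t), dim)).
    """
    if dim % 2 != 0:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t_arr < 0):
        raise ValueError("time step must be non-negative")
    half = dim // 2
    exponents = np.arange(half) / max(half - 1, 1)
    omega = 10000.0**exponents  # 1 .. 10000, geometric
    angles = t_arr[:, None] / omega[None, :]
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
    return emb[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else emb


@dataclass
class DenoiserConfig:
    """Architecture of the noise-prediction U-Net.

    ``attention_levels`` indexes resolution levels 0..depth, where
    ``depth`` is the bottleneck; the default places one attention block
    at the bottleneck. ``image_size``, when given, is validated against
    ``depth`` at build time.
    """

    K: int = 3
    base_channels: int = 16
    depth: int = 2
    attention_levels: tuple[int, ...] | None = None
    time_embed_dim: int = 64
    image_size: int | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.attention_levels is None:
            self.attention_levels = (self.depth,)
        self.attention_levels = tuple(int(a) for a in self.attention_levels)
        if any(a < 0 or a > self.depth for a in self.attention_levels):
            raise ValueError(
                f"attention_levels {self.attention_levels} outside 0..{self.depth}")
        if self.time_embed_dim % 2:
            raise ValueError("time_embed_dim must be even")
        if self.image_size is not None and self.image_size % (2**self.depth):
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^depth={2**self.depth}")

    @property
    def in_channels(self) -> int:
        return 3 + self.K

    @property
    def out_channels(self) -> int:
        return self.K

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "base_channels": self.base_channels,
            "depth": self.depth,
            "attention_levels": list(self.attention_levels),
            "time_embed_dim": self.time_embed_dim,
            "image_size": self.image_size,
        }


@dataclass(frozen=True)
class DenoiserOutput:
    """Predicted noise ε̂, H×W×K channels-last."""

    epsilon_hat: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.epsilon_hat)):
            raise ValueError("predicted noise contains non-finite values")


class _ResBlock(_nn.Module):
    """GN → SiLU → conv, add time projection, GN → SiLU → conv, + skip."""

    def __init__(self, c_in: int, c_out: int, temb_dim: int, rng):
        self.norm1 = _nn.GroupNorm(8, c_in)
        self.conv1 = _nn.Conv2d(c_in, c_out, 3, rng)
        self.temb_proj = _nn.Linear(temb_dim, c_out, rng)
        self.norm2 = _nn.GroupNorm(8, c_out)
        self.conv2 = _nn.Conv2d(c_out, c_out, 3, rng)
        self.skip = _nn.Conv2d(c_in, c_out, 1, rng, pad=0) if c_in != c_out else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        B = temb.shape[0]
        h = h + self.temb_proj(temb).reshape(B, -1, 1, 1)
        h = self.conv2(self.norm2(h).silu())
        s = self.skip(x) if self.skip is not None else x
        return h + s


class _AttnBlock(_nn.Module):
    """Single-head spatial self-attention with residual connection."""

    def __init__(self, c: int, rng):
        self.norm = _nn.GroupNorm(8, c)
        self.qkv = _nn.Linear(c, 3 * c, rng)
        self.proj = _nn.Linear(c, c, rng)
        self.c = c

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.norm(x).reshape(B, C, H * W).transpose(0, 2, 1)  # B,L,C
        qkv = self.qkv(h)
        q = qkv.slice_axis(2, 0, C)
        k = qkv.slice_axis(2, C, 2 * C)
        v = qkv.slice_axis(2, 2 * C, 3 * C)
        att = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(C))
        h = att.softmax(axis=-1) @ v
        h = self.proj(h).transpose(0, 2, 1).reshape(B, C, H, W)
        return x + h


class UNetDenoiser(_nn.Module):
    """The conditional U-Net; call via :func:`denoise` or ``forward``."""

    def __init__(self, config: DenoiserConfig, rng_seed: int):
        rng = np.random.default_rng(int(rng_seed))
        cfg = config
        self.config = cfg
        self.seed = int(rng_seed)
        td = cfg.time_embed_dim
        self.temb_mlp1 = _nn.Linear(td, td, rng)
        self.temb_mlp2 = _nn.Linear(td, td, rng)
        chans = [cfg.base_channels * 2**l for l in range(cfg.depth + 1)]
        self.stem = _nn.Conv2d(cfg.in_channels, chans[0], 3, rng)
        self.down_res, self.down_attn, self.downsamplers = [], [], []
        for l in range(cfg.depth):
            self.down_res.append(_ResBlock(chans[l], chans[l], td, rng))
            self.down_attn.append(_AttnBlock(chans[l], rng) if l in cfg.attention_levels else None)
            self.downsamplers.append(_nn.Conv2d(chans[l], chans[l + 1], 3, rng, stride=2))
        cb = chans[-1]
        self.mid_res1 = _ResBlock(cb, cb, td, rng)
        self.mid_attn = _AttnBlock(cb, rng) if cfg.depth in cfg.attention_levels else None
        self.mid_res2 = _ResBlock(cb, cb, td, rng)
        self.up_convs, self.up_res, self.up_attn = [], [], []
        for l in reversed(range(cfg.depth)):
            self.up_convs.append(_nn.Conv2d(chans[l + 1], chans[l], 3, rng))
            self.up_res.append(_ResBlock(2 * chans[l], chans[l], td, rng))
            self.up_attn.append(_AttnBlock(chans[l], rng) if l in cfg.attention_levels else None)
        self.out_norm = _nn.GroupNorm(8, chans[0])
        self.out_conv = _nn.Conv2d(chans[0], cfg.out_channels, 3, rng)

    # -- graph-building forward (used for training) ---------------------
    def forward(self, x_noisy: Tensor, condition: Tensor, t) -> Tensor:
        """x_noisy (B,K,H,W), condition (B,3,H,W), t array of steps (B,)."""
        B, _, H, W = x_noisy.shape
        if condition.shape[0] != B or condition.shape[2:] != (H, W):
            raise ValueError(
                f"condition shape {condition.shape} incompatible with mask {x_noisy.shape}")
        if H % (2**self.config.depth) or W % (2**self.config.depth):
            raise ValueError(
                f"spatial size {H}x{W} not divisible by 2^depth={2**self.config.depth}")
        temb_np = sinusoidal_time_embedding(np.atleast_1d(t).astype(np.float64),
                                            self.config.time_embed_dim)
        temb = self.temb_mlp2(self.temb_mlp1(Tensor(temb_np)).silu())
        h = self.stem(_nn.concat([condition, x_noisy], axis=1))
        skips = []
        for res, attn, down in zip(self.down_res, self.down_attn, self.downsamplers):
            h = res(h, temb)
            if attn is not None:
                h = attn(h)
            skips.append(h)
            h = down(h)
        h = self.mid_res1(h, temb)
        if self.mid_attn is not None:
            h = self.mid_attn(h)
        h = self.mid_res2(h, temb)
        for conv, res, attn, skip in zip(self.up_convs, self.up_res, self.up_attn,
                                         reversed(skips)):
            h = conv(h.upsample2x())
            h = res(_nn.concat([skip, h], axis=1), temb)
            if attn is not None:
                h = attn(h)
        return self.out_conv(self.out_norm(h).silu())

    # -- inference-only numpy path --------------------------------------
    def predict(self, x_noisy: np.ndarray, condition: np.ndarray, t) -> np.ndarray:
        """Batched ε̂ prediction, numpy in/out, channels-first, no tape."""
        out = self.forward(Tensor(x_noisy), Tensor(condition), t)
        return out.data


def build_denoiser(config: DenoiserConfig, rng_seed: int) -> UNetDenoiser:
    """Construct a seeded U-Net denoiser (deterministic initialisation)."""
    return UNetDenoiser(config, rng_seed)


def denoise(handle: UNetDenoiser, x_t: np.ndarray, condition: np.ndarray,
            t: int) -> DenoiserOutput:
    """Predict the noise in one H×W×K noisy mask given its H×W×3 condition."""
    x_t = np.asarray(x_t, dtype=np.float64)
    condition = np.asarray(condition, dtype=np.float64)
    if x_t.ndim != 3 or condition.ndim != 3:
        raise ValueError("x_t must be H×W×K and condition H×W×3")
    if x_t.shape[:2] != condition.shape[:2]:
        raise ValueError(
            f"spatial size mismatch: x_t {x_t.shape[:2]} vs condition {condition.shape[:2]}")
    xb = x_t.transpose(2, 0, 1)[None]
    cb = condition.transpose(2, 0, 1)[None]
    eps = handle.predict(xb, cb, np.array([t]))
    return DenoiserOutput(epsilon_hat=eps[0].transpose(1, 2, 0))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, handle: UNetDenoiser, schedule: NoiseSchedule) -> None:
    """Parameters + architecture + schedule + init seed in one .npz archive."""
    meta = json.dumps({
        "config": handle.config.to_dict(),
        "schedule": schedule.to_config(),
        "seed": handle.seed,
    })
    state = handle.state_dict()
    np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[UNetDenoiser, NoiseSchedule]:
    with np.load(str(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = DenoiserConfig(
        K=meta["config"]["K"],
        base_channels=meta["config"]["base_channels"],
        depth=meta["config"]["depth"],
        attention_levels=tuple(meta["config"]["attention_levels"]),
        time_embed_dim=meta["config"]["time_embed_dim"],
        image_size=meta["config"]["image_size"],
    )
    handle = build_denoiser(config, meta["seed"])
    handle.load_state_dict(state)
    return handle, NoiseSchedule.from_config(meta["schedule"])
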