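"""Pure diffusion mathematics: noise schedules, closed-form forward
corruption, the noise-matching loss, and algebraic inversions.

The forward process corrupts an encoded mask x₀ through a Markov chain

    x_t = sqrt(1 - β_t) x_{t-1} + sqrt(β_t) ε,    ε ~ N(0, I),

with a predefined variance schedule β₁..β_T. Writing α_t = 1 − β_t and
ᾱ_t = Π_{s≤t} α_s, the marginal at any step has the closed form

    x_t = sqrt(ᾱ_t) x₀ + sqrt(1 − ᾱ_t) ε,

which is what training uses (no sequential simulation needed). All
indices here are 1-based, matching the usual diffusion notation; the
arrays inside ``NoiseSchedule`` are 0-based storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSchedule",
    "DiffusionSample",
    "linear_schedule",
    "forward_step",
    "q_sample",
    "invert_q_sample",
    "diffusion_loss",
]

DEFAULT_BETA_START = 1e-4
DEFAULT_BETA_END = 0.02


@dataclass(frozen=True)
class NoiseSchedule:
    """The β/α/ᾱ sequences governing forward corruption and reverse sampling.

    Attributes
    ----------
    T : int
        Number of diffusion steps.
    beta : ndarray, shape (T,)
        Per-step variances β₁..β_T, each in (0, 1).
    alpha : ndarray, shape (T,)
        α_t = 1 − β_t.
    alpha_bar : ndarray, shape (T,)
        Cumulative products ᾱ_t = Π_{s≤t} α_s (strictly decreasing).
    family : str
        Schedule family tag; only "linear" is built in.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray = field(repr=False, default=None)
    alpha_bar: np.ndarray = field(repr=False, default=None)
    family: str = "linear"

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.shape != (self.T,):
            raise ValueError(f"beta must have shape ({self.T},), got {beta.shape}")
        if np.any(beta <= 0.0) or np.any(beta >= 1.0):
            raise ValueError("beta: every value must lie strictly in (0, 1)")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", 1.0 - beta)
        object.__setattr__(self, "alpha_bar", np.cumprod(1.0 - beta))

    # 1-based accessors used by every operation below
    def beta_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.beta[t - 1])

    def alpha_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha[t - 1])

    def alpha_bar_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha_bar[t - 1])

    def _check_t(self, t: int) -> None:
        if not (1 <= int(t) <= self.T):
            raise ValueError(f"t={t} outside schedule range 1..{self.T}")

    def to_config(self) -> dict:
        """Plain-text serialisable description (linear family only)."""
        return {
            "T": int(self.T),
            "beta_start": float(self.beta[0]),
            "beta_end": float(self.beta[-1]),
            "family": self.family,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NoiseSchedule":
        if cfg.get("family", "linear") != "linear":
            raise ValueError(f"unsupported schedule family {cfg.get('family')!r}")
        return linear_schedule(int(cfg["T"]), float(cfg["beta_start"]), float(cfg["beta_end"]))


@dataclass(frozen=True)
class DiffusionSample:
    """A corrupted map x_t together with the step t and noise draw used."""

    x_t: np.ndarray
    t: int
    epsilon: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.x_t)):
            raise ValueError("x_t contains non-finite values")


def linear_schedule(T: int, beta_start: float = DEFAULT_BETA_START,
                    beta_end: float = DEFAULT_BETA_END) -> NoiseSchedule:
    """Linear variance schedule with β_t evenly spaced from start to end.

    For T == 1 the single variance is ``beta_start``.
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"require 0 < beta_start <= beta_end < 1, got beta_start={beta_start}, "
            f"beta_end={beta_end}")
    beta = np.linspace(beta_start, beta_end, int(T))
    return NoiseSchedule(T=int(T), beta=beta, family="linear")


def _check_shapes(a: np.ndarray, b: np.ndarray, names: str) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch between {names}: {np.shape(a)} vs {np.shape(b)}")


def forward_step(x_prev, t: int, epsilon, schedule: NoiseSchedule) -> np.ndarray:
    """One Markov corruption step: sqrt(1−β_t)·x_{t−1} + sqrt(β_t)·ε."""
    x_prev = np.asarray(x_prev, dtype=np.float64)
    epsilon = np.asarray(epsilon, dtype=np.float64)
    _check_shapes(x_prev, epsilon, "x_prev and epsilon")
    beta_t = schedule.beta_at(t)
    return np.sqrt(1.0 - beta_t) * x_prev + np.sqrt(beta_t) * epsilon


def q_sample(x0, t: int, epsilon, schedule: NoiseSchedule) -> DiffusionSample:
    """Closed-form jump to step t: x_t = sqrt(ᾱ_t)·x₀ + sqrt(1−ᾱ_t)·ε."""
    x0 = np.asarray(x0, dtype=np.float64)
    epsilon = np.asarray(epsilon, dtype=np.float64)
    _check_shapes(x0, epsilon, "x0 and epsilon")
    abar = schedule.alpha_bar_at(t)
    x_t = np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * epsilon
    return DiffusionSample(x_t=x_t, t=int(t), epsilon=epsilon)


def invert_q_sample(x_t, epsilon, t: int, schedule: NoiseSchedule) -> np.ndarray:
    """Solve the closed-form corruption for x₀ given the noise draw.

    Returns (x_t − sqrt(1−ᾱ_t)·ε) / sqrt(ᾱ_t); when ᾱ_t == 1 the noise
    term vanishes and x_t is returned directly.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    epsilon = np.asarray(epsilon, dtype=np.float64)
    _check_shapes(x_t, epsilon, "x_t and epsilon")
    abar = schedule.alpha_bar_at(t)
    if abar == 0.0:
        raise ValueError("degenerate schedule: alpha_bar(t) == 0")
    if abar == 1.0:
        return x_t.copy()
    return (x_t - np.sqrt(1.0 - abar) * epsilon) / np.sqrt(abar)


def diffusion_loss(epsilon_real, epsilon_pred) -> float:
    """Noise-matching objective: batch mean of per-sample squared L2 norms.

    The leading axis indexes the batch; each sample's squared error is
    summed over all of its elements, then averaged over the m samples.
    """
    er = np.asarray(epsilon_real, dtype=np.float64)
    ep = np.asarray(epsilon_pred, dtype=np.float64)
    _check_shapes(er, ep, "epsilon_real and epsilon_pred")
    if er.shape[0] == 0 or er.ndim == 0:
        raise ValueError("empty batch: need at least one sample on the leading axis")
    m = er.shape[0]
    diff = (er - ep).reshape(m, -1)
    return float(np.mean(np.sum(diff * diff, axis=1)))
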