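"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the denoising U-Net, the convolutional
backbones and the attention-based fusion heads need: broadcasted
arithmetic, (grouped) 2-D convolution via im2col, nearest-neighbour
upsampling, softmax, normalisation layers, multi-head attention and an
AdamW optimiser with linear learning-rate warmup.

Arrays are float64 throughout; model tensors use the NCHW layout.
Gradients are accumulated on ``Tensor.grad`` by ``Tensor.backward()``
over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "LayerNorm",
    "MultiheadAttention",
    "AdamW",
    "concat",
    "stack_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode AD."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph mechanics ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._parents:
                t._backward = None  # release closures once used
        # free intermediate grads to keep memory flat across steps
        for t in topo:
            if t._parents:
                t.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        need = self.requires_grad or self._parents or other.requires_grad or other._parents
        if not need:
            return Tensor(out_data)

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __neg__(self):
        return self * -1.0

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, parents=(self,), backward=None)

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def silu(self) -> "Tensor":
        """x * sigmoid(x) — the swish-family activation used throughout."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g * s * (1.0 + self.data * (1.0 - s)))
        return out

    def relu(self) -> "Tensor":
        m = self.data > 0
        out = Tensor(self.data * m, parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g * m)
        return out

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=None)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g.reshape(old))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,), backward=None)
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=None)

        def backward(g):
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,), backward=None)

        def backward(g):
            self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = backward
        return out

    def slice_axis(self, axis: int, start: int, stop: int) -> "Tensor":
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, stop)
        idx = tuple(idx)
        out = Tensor(self.data[idx], parents=(self,), backward=None)

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        out._backward = backward
        return out

    # -- spatial ops ----------------------------------------------------
    def upsample2x(self) -> "Tensor":
        """Nearest-neighbour 2x upsampling of NCHW maps."""
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        out = Tensor(out_data, parents=(self,), backward=None)
        B, C, H, W = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

        out._backward = backward
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors), backward=None)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        ofs = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(ofs, ofs + s)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(idx)])
            ofs += s

    out._backward = backward
    return out


def stack_rows(tensors) -> Tensor:
    """Stack a list of equal-shape tensors along a new leading axis."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors]), parents=tuple(tensors), backward=None)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad or t._parents:
                t._accumulate(g[i])

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution primitive
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    OH = (H + 2 * pad - kh) // stride + 1
    OW = (W + 2 * pad - kw) // stride + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, OH, OW),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(cols), OH, OW


def _col2im(gcols: np.ndarray, x_shape, kh, kw, stride, pad):
    B, C, H, W = x_shape
    gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=np.float64)
    OH, OW = gcols.shape[-2:]
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i:i + OH * stride:stride, j:j + OW * stride:stride] += gcols[:, :, i, j]
    if pad:
        return gxp[:, :, pad:H + pad, pad:W + pad]
    return gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 1, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution, NCHW input, weight (OC, C//G, kh, kw)."""
    B, C, H, W = x.data.shape
    OC, Cg, kh, kw = w.data.shape
    G = groups
    assert C == Cg * G and OC % G == 0
    cols, OH, OW = _im2col(x.data, kh, kw, stride, pad)  # B,C,kh,kw,OH,OW
    colsm = cols.reshape(B, G, Cg * kh * kw, OH * OW)
    wm = w.data.reshape(G, OC // G, Cg * kh * kw)
    out_data = np.matmul(wm[None], colsm).reshape(B, OC, OH, OW)
    out = Tensor(out_data, parents=tuple(p for p in (x, w, b) if p is not None), backward=None)

    def backward(g):
        gm = g.reshape(B, G, OC // G, OH * OW)
        if w.requires_grad or w._parents:
            if G == 1:
                gw = np.tensordot(gm[:, 0], colsm[:, 0], axes=([0, 2], [0, 2]))
            else:
                gw = np.einsum("bgol,bgcl->goc", gm, colsm, optimize=True)
            w._accumulate(gw.reshape(OC, Cg, kh, kw))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = np.matmul(np.swapaxes(wm, -1, -2)[None], gm)
            gcols = gcols.reshape(B, C, kh, kw, OH, OW)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint holds {len(state)} arrays, model has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, groups: int = 1):
        pad = (k // 2) if pad is None else pad
        fan_in = (c_in // groups) * k * k
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in // groups, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad, self.groups = stride, pad, groups

    def __call__(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.w, None, stride=self.stride, pad=self.pad, groups=self.groups)
        return y + self.b.reshape(1, -1, 1, 1)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.groups, self.eps = min(groups, channels), eps

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        G = self.groups
        xg = x.reshape(B, G, (C // G) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps).pow(-0.5)
        xn = xn.reshape(B, C, H, W)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class MultiheadAttention(Module):
    """Scaled dot-product attention over (B, L, D) token sequences.

    Called with distinct query and key/value inputs it performs
    cross-attention; with the same input, self-attention.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"heads={heads} must divide embed_dim={dim}")
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.heads, self.dim = heads, dim

    def __call__(self, q_in: Tensor, kv_in: Tensor) -> Tensor:
        B, Lq, D = q_in.shape
        Lk = kv_in.shape[1]
        h, dh = self.heads, D // self.heads
        q = self.q_proj(q_in).reshape(B, Lq, h, dh).transpose(0, 2, 1, 3)
        k = self.k_proj(kv_in).reshape(B, Lk, h, dh).transpose(0, 2, 1, 3)
        v = self.v_proj(kv_in).reshape(B, Lk, h, dh).transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.out_proj(out)


class AdamW:
    """AdamW with decoupled weight decay and linear warmup."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, warmup_steps: int = 0,
                 total_steps: int | None = None, grad_clip: float | None = None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay, self.warmup_steps = weight_decay, warmup_steps
        self.total_steps, self.grad_clip = total_steps, grad_clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def current_lr(self) -> float:
        if self.warmup_steps > 0 and self.t < self.warmup_steps:
            return self.lr * (self.t + 1) / self.warmup_steps
        if self.total_steps and self.total_steps > self.warmup_steps:
            # cosine decay from the end of warmup to the final step
            frac = (self.t - self.warmup_steps) / (self.total_steps - self.warmup_steps)
            return self.lr * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
        return self.lr

    def _clip_grads(self) -> None:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float(np.sum(p.grad * p.grad))
        norm = np.sqrt(total)
        if norm > self.grad_clip:
            scale = self.grad_clip / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        if self.grad_clip is not None:
            self._clip_grads()
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
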