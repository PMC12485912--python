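"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly what the surrogate sequence-to-expression model needs:
dilated same-padding 1-D convolutions, GELU/ReLU, a position-wise channel
mixer, layer normalisation, dense layers, an AdamW optimizer and the
warm-up + cosine learning-rate schedule.  All layers cache their forward
inputs and support a single backward pass per forward call.

Shapes follow the (batch, length, channels) convention for sequence
layers and (batch, features) for dense layers.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.v = np.ascontiguousarray(value)
        self.g = np.zeros_like(self.v)
        self.decay = decay  # whether weight decay applies (not for biases/norm)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padding dilated 1-D convolution, (B, L, C) -> (B, L, O).

    Uses the im2col formulation — tap slices are concatenated along the
    channel axis and contracted in one BLAS matmul, the fastest
    pure-numpy formulation at these sizes.  The weight is stored flat as
    (kernel * in_ch, out_ch); tap k occupies rows [k*C, (k+1)*C).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (in_ch * kernel))
        self.W = Param((rng.standard_normal((kernel * in_ch, out_ch)) * scale).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype), decay=False)
        self.in_ch = in_ch
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2
        self._patches: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        patches = np.concatenate(
            [xp[:, k * self.dilation:k * self.dilation + L, :] for k in range(self.kernel)],
            axis=2,
        )
        self._patches = patches
        self._shape = (B, L, C)
        y = patches.reshape(B * L, -1) @ self.W.v + self.b.v
        return y.reshape(B, L, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        dyf = dy.reshape(B * L, -1)
        self.W.g += self._patches.reshape(B * L, -1).T @ dyf
        self.b.g += dyf.sum(axis=0)
        dp = (dyf @ self.W.v.T).reshape(B, L, self.kernel * C)
        dxp = np.zeros((B, L + 2 * self.pad, C), dtype=dy.dtype)
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, off:off + L, :] += dp[:, :, k * C:(k + 1) * C]
        return dxp[:, self.pad:self.pad + L, :] if self.pad else dxp


class PosReadout(Layer):
    """Position-resolved linear readout fused with global average pooling.

    Algebraically the composition of a per-position channel mix (not
    translation equivariant, so individual positions can carry distinct
    effects — the positional capacity a large trunk would provide) and
    mean pooling over the positional axis, with the 1/L constant absorbed
    into the learned weights: z[b,k] = sum_{c,l} W[(c,l),k] x[b,c,l].
    Fusing the two keeps the whole layer a single BLAS matmul and keeps
    per-position weights on an optimizer-reachable scale.
    """

    def __init__(self, in_ch: int, out_dim: int, length: int,
                 rng: np.random.Generator | None = None, scale: float = 0.01,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = Param((rng.standard_normal((in_ch * length, out_dim)) * scale).astype(dtype))
        self._xf: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._xf = x.reshape(x.shape[0], -1)
        return self._xf @ self.W.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += self._xf.T @ dy
        return (dy @ self.W.v.T).reshape(self._shape)


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0).astype(x.dtype)))
        return x * self._cdf

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (self._cdf + x * pdf).astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LayerNorm(Layer):
    """Feature-axis layer normalisation with affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(dim, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(dim, dtype=dtype), decay=False)
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.v * self._xhat + self.beta.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.g += (dy * xhat).sum(axis=0)
        self.beta.g += dy.sum(axis=0)
        dxhat = dy * self.gamma.v
        d = xhat.shape[1]
        return (inv / d) * (
            d * dxhat - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / in_dim)
        self.W = Param((rng.standard_normal((in_dim, out_dim)) * scale).astype(dtype))
        self.b = Param(np.zeros(out_dim, dtype=dtype), decay=False)

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T


class AdamW:
    """AdamW with decoupled weight decay (decay skipped for flagged params)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.v, dtype=np.float32) for p in params]
        self.s = [np.zeros_like(p.v, dtype=np.float32) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, s in zip(self.params, self.m, self.s):
            g = p.g
            m *= b1
            m += (1 - b1) * g
            s *= b2
            s += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(s / bc2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.v
            p.v -= (lr * update).astype(p.v.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def lr_schedule(step: int, total_steps: int, peak: float,
                warmup_frac: float = 0.1) -> float:
    """Linear warm-up over the first ``warmup_frac`` of steps to ``peak``,
    then cosine decay to exactly 0 at ``total_steps``."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    warmup = warmup_frac * total_steps
    if warmup > 0 and step < warmup:
        return peak * step / warmup
    denom = max(total_steps - warmup, 1e-12)
    phase = (step - warmup) / denom
    return peak * 0.5 * (1.0 + math.cos(math.pi * min(phase, 1.0)))
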