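"""Minimal NumPy neural-network layer engine with explicit backpropagation.

The super-resolution model in this package is small enough to train on a
single CPU, so layers are implemented directly on NumPy arrays with
hand-written backward passes instead of relying on an autodiff framework.
Every layer caches what its backward pass needs during ``forward`` and
consumes the cache in ``backward``; a layer instance is therefore used at
most once per forward/backward cycle (which the static model graphs here
guarantee).

Conventions: the engine stores activations channels-LAST, ``(B, H, W, C)``,
so that im2col gathers, window partitioning and per-token layers all touch
contiguous runs of memory (the training loop is memory-bound on modest
hardware, not FLOP-bound).  The public model API still speaks the
channels-first ``(C, H, W)`` convention and converts at the boundary.
Gradients accumulate into ``Parameter.grad`` until ``zero_grad`` is called.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

DEFAULT_DTYPE = np.float32

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size


class Module:
    """Base class: recursive parameter discovery over instance attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def trunc_normal(rng: np.random.Generator, shape, std=0.02, dtype=DEFAULT_DTYPE):
    """Normal(0, std) truncated to +-2 std (clipped), the usual transformer init."""
    return (np.clip(rng.standard_normal(shape), -2.0, 2.0) * std).astype(dtype)


def fan_uniform(rng: np.random.Generator, shape, fan_in, dtype=DEFAULT_DTYPE):
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)), the common conv default."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    """2-D convolution with 'same' zero padding, one GEMM per kernel tap.

    Only odd kernel sizes are supported (padding ``k // 2`` keeps the
    spatial size).  Layout is channels-last: ``(B, H, W, C)``; the weight
    is stored ``(k, k, in_ch, out_ch)``.  Accumulating ``k^2`` shifted
    GEMMs re-reads one activation-sized array per tap instead of
    materialising a ``k^2``-times-larger im2col matrix, which keeps the
    working set cache-resident on memory-bound hardware.
    """

    def __init__(self, in_ch, out_ch, kernel_size, rng, dtype=DEFAULT_DTYPE):
        if kernel_size % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel size")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = kernel_size
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Parameter(fan_uniform(
            rng, (kernel_size, kernel_size, in_ch, out_ch), fan_in, dtype))
        self.bias = Parameter(fan_uniform(rng, (out_ch,), fan_in, dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, p = self.k, self.k // 2
        w = self.weight.data
        if k == 1:
            xf = x.reshape(-1, C)
            self._cache = (x, None)
            y = xf @ w.reshape(C, self.out_ch) + self.bias.data
            return y.reshape(B, H, W, self.out_ch)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        y = np.empty((B * H * W, self.out_ch), dtype=x.dtype)
        y[:] = self.bias.data
        for ki in range(k):
            for kj in range(k):
                tap = np.ascontiguousarray(
                    xp[:, ki:ki + H, kj:kj + W, :]).reshape(-1, C)
                y += tap @ w[ki, kj]
        self._cache = (xp, x.shape)
        return y.reshape(B, H, W, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        w = self.weight.data
        if k == 1:
            x, _ = self._cache
            self._cache = None
            B, H, W, C = x.shape
            dyf = dy.reshape(-1, self.out_ch)
            self.weight.grad += (x.reshape(-1, C).T @ dyf).reshape(self.weight.shape)
            self.bias.grad += dyf.sum(axis=0)
            return (dyf @ w.reshape(C, self.out_ch).T).reshape(B, H, W, C)
        xp, (B, H, W, C) = self._cache
        self._cache = None
        dyf = dy.reshape(B * H * W, self.out_ch)
        self.bias.grad += dyf.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                tap = np.ascontiguousarray(
                    xp[:, ki:ki + H, kj:kj + W, :]).reshape(-1, C)
                self.weight.grad[ki, kj] += tap.T @ dyf
                dxp[:, ki:ki + H, kj:kj + W, :] += (dyf @ w[ki, kj].T).reshape(B, H, W, C)
        return np.ascontiguousarray(dxp[:, p:p + H, p:p + W, :])


class Linear(Module):
    """Affine map over the last axis of an arbitrary-rank input."""

    def __init__(self, in_features, out_features, rng, std=0.02, dtype=DEFAULT_DTYPE):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features), std, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xf = x.reshape(-1, self.in_features)
        self._cache = (xf, x.shape)
        y = xf @ self.weight.data.T + self.bias.data
        return y.reshape(*x.shape[:-1], self.out_features)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, xshape = self._cache
        self._cache = None
        dyf = dy.reshape(-1, self.out_features)
        self.weight.grad += dyf.T @ xf
        self.bias.grad += dyf.sum(axis=0)
        return (dyf @ self.weight.data).reshape(xshape)


class LayerNorm(Module):
    """Layer normalization over the last (channel) axis, with affine scale/shift."""

    def __init__(self, dim, eps=1e-5, dtype=DEFAULT_DTYPE):
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.data + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += np.sum(dy, axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.data
        n = self.dim
        return (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * np.mean(dxhat * xhat, axis=-1, keepdims=True)) * inv


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        self._cache = (x, cdf)
        return x * cdf

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, cdf = self._cache
        self._cache = None
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
        return dy * (cdf + x * pdf)


class PixelShuffle(Module):
    """Sub-pixel rearrangement, channels-last:
    (B, H, W, C*r^2) -> (B, H*r, W*r, C)."""

    def __init__(self, r):
        self.r = r
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        B, H, W, C = x.shape
        r = self.r
        if C % (r * r) != 0:
            raise ValueError(f"channel count {C} not divisible by r^2 = {r * r}")
        c = C // (r * r)
        # channel index decomposes as c*r^2 + (y % r)*r + (x % r)
        y = x.reshape(B, H, W, c, r, r).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y).reshape(B, H * r, W * r, c)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        r = self.r
        c = C // (r * r)
        d = dy.reshape(B, H, r, W, r, c).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(d).reshape(B, H, W, C)


def pixel_shuffle(feat: np.ndarray, r: int) -> np.ndarray:
    """Rearrange a ``C*r^2`` channel map into a ``C`` channel map ``r``x larger.

    ``out[c, y, x] = in[c*r^2 + (y % r)*r + (x % r), y // r, x // r]``.
    Accepts ``(C, H, W)`` or ``(B, C, H, W)``.
    """
    if r < 1:
        raise ValueError("upsampling factor must be >= 1")
    squeeze = feat.ndim == 3
    x = feat[None] if squeeze else feat
    if x.ndim != 4:
        raise ValueError("expected a (C, H, W) or (B, C, H, W) array")
    B, C, H, W = x.shape
    if C % (r * r) != 0:
        raise ValueError(f"channel count {C} not divisible by r^2 = {r * r}")
    c = C // (r * r)
    y = x.reshape(B, c, r, r, H, W).transpose(0, 1, 4, 2, 5, 3)
    y = np.ascontiguousarray(y).reshape(B, c, H * r, W * r)
    return y[0] if squeeze else y


class Adam:
    """Adam with bias correction and optional global-norm gradient clipping."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8, grad_clip=None):
        self.params = list(params)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self, lr: float):
        if self.grad_clip is not None:
            sq = sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.params)
            norm = np.sqrt(sq)
            scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        else:
            scale = 1.0
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad * scale
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            update = lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= update.astype(p.data.dtype)

    def state_dict(self) -> dict:
        out = {"t": np.int64(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i][...] = state[f"m{i}"]
            self.v[i][...] = state[f"v{i}"]


def global_grad_norm(params) -> float:
    return float(np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in params)))
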