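"""Neural-network layers and optimization on top of :mod:`pestfusion.autodiff`.

Layers follow the familiar Module/Parameter pattern: a :class:`Module`
owns named :class:`Parameter` tensors and child modules, and
``parameters()`` walks the tree.  Initialization is explicit — every
module takes a ``numpy.random.Generator`` so that a single seed pins
all weights.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "LayerNorm", "InstanceNorm2d",
    "RMSNorm",
    "MultiHeadAttention", "AdamW", "clip_grad_norm", "adaptive_avg_pool2d",
    "sinusoidal_positions_2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(
            -bound, bound, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(width))
        self.bias = Parameter(np.zeros(width))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with learnable affine.

    Keeps conv-stack activations at unit scale without batch coupling,
    so single-image inference matches training exactly.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(-2, -1), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(-2, -1), keepdims=True)
        norm = (x - mu) / (var + self.eps).sqrt()
        return norm * self.weight.reshape(1, -1, 1, 1) \
            + self.bias.reshape(1, -1, 1, 1)


class RMSNorm(Module):
    def __init__(self, width: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(width))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        rms = ((x ** 2).mean(axis=-1, keepdims=True) + self.eps).sqrt()
        return x / rms * self.weight


class MultiHeadAttention(Module):
    """Scaled dot-product attention, Softmax(QK^T/sqrt(d_head))V, h heads.

    Inputs are token matrices (..., N, d_model); query/key/value sources
    may differ (cross-attention).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        *batch, n, _ = x.shape
        return x.reshape(*batch, n, self.n_heads, self.d_head).transpose(
            *range(len(batch)), len(batch) + 1, len(batch), len(batch) + 2)

    def forward(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        *batch, nq, _ = query.shape
        q, k, v = self._split(self.wq(query)), self._split(self.wk(key)), \
            self._split(self.wv(value))
        scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) \
            * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        out = attn @ v
        out = out.transpose(*range(len(batch)), len(batch) + 1, len(batch),
                            len(batch) + 2).reshape(*batch, nq, self.d_model)
        return self.wo(out)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average-pool NCHW (or CHW) input to a fixed spatial size.

    Requires the input dims to be integer multiples of the output dims,
    which holds for every configuration the model uses.
    """
    oh, ow = out_hw
    *lead, h, w = x.shape
    if h % oh or w % ow:
        raise ValueError(f"adaptive pool needs divisible sizes, got {h}x{w} -> {oh}x{ow}")
    fh, fw = h // oh, w // ow
    x = x.reshape(*lead, oh, fh, ow, fw)
    return x.mean(axis=(-3, -1))


def sinusoidal_positions_2d(h: int, w: int, d_model: int) -> np.ndarray:
    """Fixed 2-D sine/cosine positional encoding, (h*w, d_model)."""
    if d_model % 4:
        raise ValueError("d_model must be divisible by 4 for 2-D encodings")
    d_quarter = d_model // 4
    freqs = np.exp(-math.log(10000.0) * np.arange(d_quarter) / d_quarter)
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ya = ys.reshape(-1, 1) * freqs
    xa = xs.reshape(-1, 1) * freqs
    return np.concatenate([np.sin(ya), np.cos(ya), np.sin(xa), np.cos(xa)], axis=1)


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total
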