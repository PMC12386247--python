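"""Environment-guided modality attention (EMA).

Field conditions decide which imaging modality can be trusted: thermal
dominates in fog and at dusk, RGB at bright noon.  This module encodes
a short history of (temperature, humidity, light) readings with a
state-space stack and turns the result into a spatial, channel-wise
modulation gate ``g`` in (0,1) plus a learnable scalar mixing
coefficient ``alpha``; the fused visual features are

    F_fused(i,j,c) = g(i,j,c) * [alpha * F_RGB(i,j,c) + (1-alpha) * F_IR(i,j,c)].

The state-space core is the linear recurrence

    h_t = A h_{t-1} + B x_t,    y_t = C_out h_t,    h_0 = 0,

with a diagonal ``A`` sigmoid-bounded in (0,1) so the recurrence is
stable at initialization.  Each of the L=3 stack layers wraps the
recurrence with RMS normalization, a width-64 linear map, a depthwise
temporal convolution (kernel 3, same padding) and a SiLU activation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, stack
from .config import ModelConfig
from .nn import Linear, Module, Parameter, RMSNorm

__all__ = ["SS1D", "SSMLayer", "EnvGate", "fuse"]


class SS1D(Module):
    """Linear state-space recurrence over a (batched) sequence.

    Input (N, T, D) -> output sequence (N, T, D); ``A`` is diagonal with
    entries sigmoid(a) in (0,1) (spectral radius < 1), ``B`` and
    ``C_out`` are dense.
    """

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.a_logit = Parameter(rng.normal(0.0, 0.5, width))
        bound = 1.0 / np.sqrt(width)
        self.b = Parameter(rng.uniform(-bound, bound, (width, width)))
        self.c_out = Parameter(rng.uniform(-bound, bound, (width, width)))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:          # (T, D) convenience
            return self.forward(x.reshape(1, *x.shape)).reshape(x.shape)
        n, t, d = x.shape
        a = self.a_logit.sigmoid()
        h = Tensor(np.zeros((n, d)))
        ys = []
        for step in range(t):
            h = h * a + x[:, step, :] @ self.b
            ys.append(h @ self.c_out)
        return stack(ys, axis=1)


class SSMLayer(Module):
    """RMSNorm -> linear(width) -> depthwise conv(k=3, same) -> SiLU -> SS1D."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.norm = RMSNorm(width)
        self.lin = Linear(width, width, rng)
        self.dw_kernel = Parameter(rng.normal(0.0, 0.3, (3, width)))
        self.ssm = SS1D(width, rng)

    def _depthwise(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        zero = Tensor(np.zeros((n, 1, d)))
        padded = concat([zero, x, zero], axis=1)
        return (padded[:, 0:t, :] * self.dw_kernel[0]
                + padded[:, 1:t + 1, :] * self.dw_kernel[1]
                + padded[:, 2:t + 2, :] * self.dw_kernel[2])

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(x)
        y = self.lin(y)
        y = self._depthwise(y)
        y = y.silu()
        return x + self.ssm(y)          # residual keeps the stack trainable


class EnvGate(Module):
    """Project env history through the SSM stack into the modulation gate."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        width = cfg.env_width
        self.layers = [SSMLayer(width, rng) for _ in range(cfg.ema_depth)]
        self.spatial = Linear(width, cfg.gate_hw * cfg.gate_hw, rng)
        self.channel = Linear(width, cfg.gate_channels, rng)
        # open-gate initialization (cf. LSTM forget-gate bias): the gate
        # starts near 1 so it attenuates nothing until the environment
        # signal earns influence
        self.gate_bias = Parameter(np.full(1, 2.0))
        self.alpha_logit = Parameter(np.zeros(1))   # sigmoid(0) = 0.5

    @property
    def alpha(self) -> Tensor:
        return self.alpha_logit.sigmoid()

    def guidance(self, env_embeddings: Tensor) -> Tensor:
        """SSM stack over (N, T, width) embeddings; returns final y_T (N, width)."""
        if env_embeddings.ndim == 2:
            env_embeddings = env_embeddings.reshape(1, *env_embeddings.shape)
        if env_embeddings.shape[1] < 1:
            raise ValueError("empty environment sequence")
        y = env_embeddings
        for layer in self.layers:
            y = layer(y)
        return y[:, -1, :]

    def build_gate(self, env_embeddings: Tensor) -> Tensor:
        """Gate tensor (N, C, H, W), every entry in (0, 1)."""
        g = self.guidance(env_embeddings)
        hw, c = self.cfg.gate_hw, self.cfg.gate_channels
        spatial_logits = self.spatial(g).reshape(-1, 1, hw, hw)
        channel_logits = self.channel(g).reshape(-1, c, 1, 1)
        return (spatial_logits + channel_logits + self.gate_bias).sigmoid()


def fuse(f_rgb: Tensor, f_ir: Tensor, gate: Tensor, alpha: Tensor) -> Tensor:
    """Gated convex fusion of the two modality maps (see module docstring)."""
    if f_rgb.shape != f_ir.shape:
        raise ValueError("modality maps must share shape")
    if gate.shape[-3:] != f_rgb.shape[-3:]:
        raise ValueError(f"gate shape {gate.shape} does not match features "
                         f"{f_rgb.shape}")
    return gate * (alpha * f_rgb + (1.0 - alpha) * f_ir)
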