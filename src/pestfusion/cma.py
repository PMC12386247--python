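"""Cross-modal attention-guided feature fusion.

The RGB and thermal feature maps frequently disagree: foliage that is
bright in RGB is thermally flat, a warm insect body can be nearly
invisible at dusk in RGB.  This module measures that disagreement
locally and fuses the two maps so that consistent regions dominate:

1. *Density estimation* — per local region (a ``grid x grid`` partition
   of the map) the channel-pooled activation energy is summarised as a
   smoothed B-bin histogram.
2. *KL inconsistency field* — ``D_KL(P_rgb || P_ir)`` per region scores
   how differently the modalities respond there.
3. *Alignment attention* — regions are down-weighted by
   ``w = exp(-D_KL / tau)``; zero divergence keeps weight 1.
4. *Multi-scale projection* — a 1x1 reduction to C'=32 channels plus a
   3x3 context branch, then a convolutional spatial gate.
5. *Bidirectional cross attention* — spatial tokens of one modality
   attend to the other (``Softmax(QK^T / sqrt(d)) V``), enhancing each
   stream with the other's evidence.
6. *Residual gating* — ``out = original + sigmoid(gamma) * enhanced``
   per channel, so neither modality can dominate; a learned 1x1 merge
   of the two gated streams yields the C'xHxW fused map.

The histogram/KL statistics are descriptive (computed on activations,
no gradient flows through them); everything else is differentiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import ModelConfig
from .encoders import FeatureMap
from .nn import Conv2d, Linear, Module

__all__ = ["ProbHistogram", "AlignmentMap", "estimate_distribution",
           "kl_divergence", "alignment_attention", "cross_attention",
           "CMAFusion"]


@dataclass
class ProbHistogram:
    """Smoothed probability histogram over B activation bins."""

    probs: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("histogram must be strictly positive after smoothing")


@dataclass
class AlignmentMap:
    """Per-region alignment weights in (0, 1]; 1 means fully consistent."""

    weights: np.ndarray   # grid x grid

    def __post_init__(self):
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite alignment weights")
        if (self.weights <= 0).any() or (self.weights > 1).any():
            raise ValueError("alignment weights must lie in (0, 1]")


def _smooth(hist: np.ndarray, bandwidth_bins: float = 1.0,
            floor: float = 1e-8) -> np.ndarray:
    """Gaussian smoothing along the bin axis + floor + renormalization."""
    n = len(hist)
    idx = np.arange(n)
    kernel = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / bandwidth_bins) ** 2)
    kernel /= kernel.sum(axis=1, keepdims=True)
    smoothed = kernel @ hist
    smoothed = np.maximum(smoothed, floor)
    return smoothed / smoothed.sum()


def estimate_distribution(fmap: np.ndarray, grid: int = 8, bins: int = 16,
                          edges: np.ndarray | None = None) -> list[list[ProbHistogram]]:
    """Per-region smoothed histograms of channel-pooled activation energy.

    ``fmap`` is CxHxW; the spatial map of per-pixel channel means is cut
    into a ``grid x grid`` partition and histogrammed over shared bin
    edges (the map's min-max range unless ``edges`` is given).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    fmap = np.asarray(fmap, dtype=float)
    energy = fmap.mean(axis=0)
    h, w = energy.shape
    if h % grid or w % grid:
        raise ValueError(f"{h}x{w} map not divisible into a {grid}x{grid} grid")
    if edges is None:
        lo, hi = float(energy.min()), float(energy.max())
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
    rh, rw = h // grid, w // grid
    out: list[list[ProbHistogram]] = []
    for gy in range(grid):
        row = []
        for gx in range(grid):
            patch = energy[gy * rh:(gy + 1) * rh, gx * rw:(gx + 1) * rw]
            if patch.size == 0:
                raise ValueError("empty region")
            counts, _ = np.histogram(patch, bins=edges)
            counts = counts.astype(float)
            # out-of-range values (shared edges) land in the boundary bins
            counts[0] += (patch < edges[0]).sum()
            counts[-1] += (patch > edges[-1]).sum()
            probs = _smooth(counts / counts.sum())
            row.append(ProbHistogram(probs, edges))
        out.append(row)
    return out


def kl_divergence(p: ProbHistogram, q: ProbHistogram) -> float:
    """D_KL(P || Q) = sum_i P(i) log(P(i)/Q(i)), natural log."""
    if p.probs.shape != q.probs.shape or not np.allclose(p.edges, q.edges):
        raise ValueError("histograms must share bin structure")
    if (q.probs <= 0).any():
        raise ValueError("Q must be strictly positive")
    mask = p.probs > 0
    return float(np.sum(p.probs[mask] * np.log(p.probs[mask] / q.probs[mask])))


def alignment_attention(kl_field: np.ndarray, tau: float = 1.0) -> AlignmentMap:
    """Monotone decreasing map from KL to a weight in (0,1]: exp(-KL/tau)."""
    kl_field = np.asarray(kl_field, dtype=float)
    if not np.isfinite(kl_field).all():
        raise ValueError("non-finite KL field")
    return AlignmentMap(np.exp(-np.clip(kl_field, 0.0, None) / tau))


def cross_attention(query_proj: Linear, key_proj: Linear, value_proj: Linear,
                    q_tokens: Tensor, kv_tokens: Tensor) -> Tensor:
    """Single-head Softmax(QK^T/sqrt(d))V over spatial tokens (..., N, C)."""
    q = query_proj(q_tokens)
    k = key_proj(kv_tokens)
    v = value_proj(kv_tokens)
    d = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / math.sqrt(d))
    return scores.softmax(axis=-1) @ v


class ResidualGate(Module):
    """out = original + sigmoid(gamma) * enhanced, per-channel gamma."""

    def __init__(self, channels: int):
        super().__init__()
        from .nn import Parameter
        self.gamma = Parameter(np.zeros(channels))

    def forward(self, original: Tensor, enhanced: Tensor) -> Tensor:
        if original.shape != enhanced.shape:
            raise ValueError("residual gate requires matching shapes")
        gate = self.gamma.sigmoid().reshape(1, -1, 1, 1)
        return original + gate * enhanced


class SpatialGate(Module):
    """Convolutional spatial attention: 7x7 conv on [mean; max] maps -> sigmoid."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, 7, rng, padding=3)

    def forward(self, x: Tensor) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True),
                         x.max(axis=1, keepdims=True)], axis=1)
        return x * self.conv(pooled).sigmoid()


class CMAFusion(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c_in, c_out = cfg.enc_channels, cfg.cma_channels
        self.reduce_rgb = Conv2d(c_in, c_out, 1, rng)
        self.reduce_ir = Conv2d(c_in, c_out, 1, rng)
        self.context_rgb = Conv2d(c_in, c_out, 3, rng, padding=1)
        self.context_ir = Conv2d(c_in, c_out, 3, rng, padding=1)
        self.spatial_rgb = SpatialGate(rng)
        self.spatial_ir = SpatialGate(rng)
        self.q_rgb = Linear(c_out, c_out, rng)
        self.k_ir = Linear(c_out, c_out, rng)
        self.v_ir = Linear(c_out, c_out, rng)
        self.q_ir = Linear(c_out, c_out, rng)
        self.k_rgb = Linear(c_out, c_out, rng)
        self.v_rgb = Linear(c_out, c_out, rng)
        self.gate_rgb = ResidualGate(c_out)
        self.gate_ir = ResidualGate(c_out)
        self.merge = Conv2d(2 * c_out, c_out, 1, rng)

    # ------------------------------------------------------------ pieces
    def alignment_weights(self, rgb: np.ndarray, ir: np.ndarray) -> AlignmentMap:
        """KL inconsistency -> per-region weights, shared bin edges."""
        grid, bins = self.cfg.cma_grid, self.cfg.cma_bins
        both = np.concatenate([rgb.mean(axis=0).ravel(), ir.mean(axis=0).ravel()])
        lo, hi = float(both.min()), float(both.max())
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        h_rgb = estimate_distribution(rgb, grid, bins, edges)
        h_ir = estimate_distribution(ir, grid, bins, edges)
        kl = np.array([[kl_divergence(h_rgb[i][j], h_ir[i][j])
                        for j in range(grid)] for i in range(grid)])
        return alignment_attention(kl, self.cfg.cma_tau)

    def _expand_weights(self, weights: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
        grid = weights.shape[0]
        h, w = hw
        return np.kron(weights, np.ones((h // grid, w // grid)))

    def project_reduce(self, fmap: Tensor, branch: str) -> Tensor:
        """Multi-scale projection to C' channels: 1x1 reduction + 3x3 context."""
        if branch == "rgb":
            return self.reduce_rgb(fmap) + self.context_rgb(fmap)
        return self.reduce_ir(fmap) + self.context_ir(fmap)

    def _tokens(self, fmap: Tensor) -> Tensor:
        n, c, h, w = fmap.shape
        return fmap.reshape(n, c, h * w).transpose(0, 2, 1)

    def _untokens(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        n, t, c = tokens.shape
        return tokens.transpose(0, 2, 1).reshape(n, c, *hw)

    # ------------------------------------------------------------ forward
    def forward(self, rgb: FeatureMap, ir: FeatureMap
                ) -> tuple[FeatureMap, Tensor, Tensor]:
        """Returns (fused C'xHxW map, gated RGB stream, gated IR stream)."""
        x_rgb, x_ir = rgb.tensor, ir.tensor
        if x_rgb.shape != x_ir.shape:
            raise ValueError("modality feature maps must share shape")
        n, _, h, w = x_rgb.shape

        if self.cfg.use_reweighting:
            maps = [self.alignment_weights(x_rgb.data[i], x_ir.data[i])
                    for i in range(n)]
            spatial = np.stack([self._expand_weights(m.weights, (h, w))
                                for m in maps])[:, None]
            weight = Tensor(spatial)          # no gradient through statistics
            x_rgb = x_rgb * weight
            x_ir = x_ir * weight

        p_rgb = self.spatial_rgb(self.project_reduce(x_rgb, "rgb"))
        p_ir = self.spatial_ir(self.project_reduce(x_ir, "ir"))

        t_rgb, t_ir = self._tokens(p_rgb), self._tokens(p_ir)
        enh_rgb = self._untokens(
            cross_attention(self.q_rgb, self.k_ir, self.v_ir, t_rgb, t_ir), (h, w))
        enh_ir = self._untokens(
            cross_attention(self.q_ir, self.k_rgb, self.v_rgb, t_ir, t_rgb), (h, w))

        g_rgb = self.gate_rgb(p_rgb, enh_rgb)
        g_ir = self.gate_ir(p_ir, enh_ir)
        fused = self.merge(concat([g_rgb, g_ir], axis=1))
        return FeatureMap(fused, "fused"), g_rgb, g_ir
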