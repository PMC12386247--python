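"""Modality-specific encoders.

Two shallow convolutional encoders map the RGB (3-channel) and thermal
(1-channel) images to CxHxW feature maps with C=64 and H=W=64 at the
published operating point; a linear environmental encoder lifts the
3-component (temperature, humidity, light) vector to a 64-dimensional
embedding.  "Shallow" is realised as ``depth`` conv blocks of
conv3x3 -> SiLU, the first two with stride 2, followed by adaptive
average pooling to the declared spatial size.  Arbitrary input sizes
(>= the declared spatial size) are first resampled bilinearly to the
canonical side ``4 * enc_spatial`` at the data level, so the declared
output shape holds for every valid input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .config import ModelConfig
from .nn import Conv2d, InstanceNorm2d, Linear, Module, adaptive_avg_pool2d

__all__ = ["FeatureMap", "RGBEncoder", "ThermalEncoder", "EnvEncoder",
           "bilinear_resize"]


@dataclass
class FeatureMap:
    """A batched NxCxHxW activation tensor with a declared modality tag."""

    tensor: Tensor
    modality: str   # {"rgb", "thermal", "fused"}

    def __post_init__(self):
        if self.modality not in ("rgb", "thermal", "fused"):
            raise ValueError(f"unknown modality tag {self.modality!r}")
        if self.tensor.ndim != 4:
            raise ValueError("FeatureMap tensors are NxCxHxW")

    @property
    def shape(self):
        return self.tensor.shape


def bilinear_resize(image: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of a CxHxW (or NxCxHxW) array, align_corners=False."""
    *lead, h, w = image.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return image
    ys = (np.arange(oh) + 0.5) * h / oh - 0.5
    xs = (np.arange(ow) + 0.5) * w / ow - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :]
    flat = image.reshape(-1, h, w)
    top = flat[:, y0[:, None], x0[None, :]] * (1 - wx) + flat[:, y0[:, None], x1[None, :]] * wx
    bot = flat[:, y1[:, None], x0[None, :]] * (1 - wx) + flat[:, y1[:, None], x1[None, :]] * wx
    out = top * (1 - wy) + bot * wy
    return out.reshape(*lead, oh, ow)


class _VisualEncoder(Module):
    def __init__(self, in_channels: int, cfg: ModelConfig, rng: np.random.Generator,
                 modality: str):
        super().__init__()
        self.cfg = cfg
        self.modality = modality
        c = cfg.enc_channels
        widths = [in_channels] + [max(c // 2, 8)] * max(cfg.enc_depth - 2, 0) + \
            [c] * min(cfg.enc_depth, 2)
        widths = widths[:cfg.enc_depth + 1]
        widths[-1] = c
        blocks, norms = [], []
        for i in range(cfg.enc_depth):
            stride = 2 if i < 2 else 1
            blocks.append(Conv2d(widths[i], widths[i + 1], 3, rng,
                                 stride=stride, padding=1))
            norms.append(InstanceNorm2d(widths[i + 1]))
        self.blocks = blocks
        self.norms = norms

    def forward(self, images: np.ndarray | Tensor) -> FeatureMap:
        """images: Nx{1,3}xH_inxW_in in [0,1], H_in, W_in >= enc_spatial."""
        if isinstance(images, Tensor):
            x = images
        else:
            images = np.asarray(images, dtype=np.float64)
            if images.ndim == 3:
                images = images[None]
            h, w = images.shape[-2:]
            if h < self.cfg.enc_spatial or w < self.cfg.enc_spatial:
                raise ValueError(f"input {h}x{w} smaller than the declared "
                                 f"feature size {self.cfg.enc_spatial}")
            size = self.cfg.input_size
            x = Tensor(bilinear_resize(images, (size, size)))
        expected = self.blocks[0].weight.shape[1]
        if x.shape[1] != expected:
            raise ValueError(f"{self.modality} encoder expects {expected} "
                             f"channels, got {x.shape[1]}")
        for block, norm in zip(self.blocks, self.norms):
            x = norm(block(x)).silu()
        x = adaptive_avg_pool2d(x, (self.cfg.enc_spatial, self.cfg.enc_spatial))
        return FeatureMap(x, self.modality)


class RGBEncoder(_VisualEncoder):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(3, cfg, rng, "rgb")


class ThermalEncoder(_VisualEncoder):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(1, cfg, rng, "thermal")


class EnvEncoder(Module):
    """Affine lift of the 3-channel environment vector to ``env_width`` dims."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(3, cfg.env_width, rng)

    def forward(self, env: np.ndarray | Tensor) -> Tensor:
        x = env if isinstance(env, Tensor) else Tensor(np.asarray(env, dtype=np.float64))
        if x.shape[-1] != 3:
            raise ValueError("environment vectors have exactly 3 components "
                             "(temperature, humidity, light)")
        if not np.isfinite(x.data).all():
            raise ValueError("environment vector must be finite")
        return self.proj(x)
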