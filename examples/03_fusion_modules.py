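"""Inspect the two fusion mechanisms on synthetic feature maps.

1. Cross-modal attention fusion scores RGB/thermal disagreement with a
   per-region KL divergence and down-weights inconsistent regions.
2. The environment-guided gate turns a sensor history into a spatial
   modulation tensor g in (0,1) and mixes modalities by Eq.-style
   gated convex combination g * [alpha*F_RGB + (1-alpha)*F_IR].
"""

import numpy as np

from pestfusion.autodiff import Tensor, no_grad
from pestfusion.cma import CMAFusion
from pestfusion.config import ModelConfig
from pestfusion.ema import EnvGate, fuse
from pestfusion.encoders import FeatureMap

cfg = ModelConfig.tiny()
rng = np.random.default_rng(0)

# two modality maps that agree on the left half and disagree on the right
base = rng.normal(size=(cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial))
ir = base.copy()
ir[:, :, cfg.enc_spatial // 2:] = rng.normal(
    3.0, 2.0, ir[:, :, cfg.enc_spatial // 2:].shape)

cma = CMAFusion(cfg, rng)
weights = cma.alignment_weights(base, ir).weights
print("alignment weights (1 = consistent, small = conflicting):")
print("  left half mean:", round(weights[:, :2].mean(), 3),
      " right half mean:", round(weights[:, 2:].mean(), 3))

with no_grad():
    fused, _, _ = cma(FeatureMap(Tensor(base[None]), "rgb"),
                      FeatureMap(Tensor(ir[None]), "thermal"))
print("fused map shape:", fused.tensor.shape)

gate_mod = EnvGate(cfg, rng)
night = np.tile([[0.4, 0.8, 0.05]], (cfg.ema_history, 1))   # dark, humid
noon = np.tile([[0.6, 0.4, 0.95]], (cfg.ema_history, 1))    # bright
with no_grad():
    from pestfusion.encoders import EnvEncoder
    enc = EnvEncoder(cfg, rng)
    g_night = gate_mod.build_gate(enc(night[None])).numpy()
    g_noon = gate_mod.build_gate(enc(noon[None])).numpy()
print(f"gate under night input: mean {g_night.mean():.3f}; "
      f"under noon input: mean {g_noon.mean():.3f} (different env -> different gate)")

f_rgb = Tensor(np.full((1, cfg.gate_channels, cfg.gate_hw, cfg.gate_hw), 2.0))
f_ir = Tensor(np.full((1, cfg.gate_channels, cfg.gate_hw, cfg.gate_hw), 4.0))
out = fuse(f_rgb, f_ir, Tensor(np.full(f_rgb.shape, 0.5)), Tensor(0.5))
print("gated fusion of constants 2 and 4 with g=0.5, alpha=0.5:",
      float(out.numpy().mean()), "(= 0.5 * (0.5*2 + 0.5*4))")
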