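"""End-to-end multimodal detector.

Dataflow (full model): the RGB and thermal images pass through their
encoders; cross-modal attention fusion yields a merged C'xHxW map plus
the two per-modality enhanced streams; the environment history drives
the state-space gate, which fuses the enhanced streams via the gated
convex combination; a learned 1x1 merge of the CMA map and the gated
map feeds the transformer set-prediction head.

Ablation switches rewire exactly one thing each:

* ``use_cma=False`` — fusion becomes channel concatenation + 1x1 conv;
  the per-modality streams are plain 1x1 projections.
* ``use_ema=False`` — the gate is identically 1; only the learnable
  scalar ``alpha`` mixes modalities.
* ``use_reweighting=False`` — ``alpha`` is frozen at 0.5 and the CMA
  KL-alignment weighting path is disabled.
* ``decoupled_head=False`` — a single query set and a single shared
  prediction head serve all 8 classes.
* missing modalities are replaced by learned constant streams so the
  rest of the network keeps its statistics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .cma import CMAFusion
from .config import ModelConfig, RunConfig
from .encoders import EnvEncoder, FeatureMap, RGBEncoder, ThermalEncoder
from .ema import EnvGate, fuse
from .head import DetectionHead
from .nn import Conv2d, Module, Parameter, adaptive_avg_pool2d

__all__ = ["PestPredatorDetector", "save_checkpoint", "load_checkpoint"]


class PestPredatorDetector(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.rgb_encoder = RGBEncoder(cfg, rng)
        if "thermal" in cfg.modalities:
            self.thermal_encoder = ThermalEncoder(cfg, rng)
        else:
            self.thermal_stub = Parameter(rng.normal(
                0, 0.1, (cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial)))
        self.env_encoder = EnvEncoder(cfg, rng)
        if "sensor" not in cfg.modalities:
            self.env_stub = Parameter(np.full(3, 0.5))
        if cfg.use_cma:
            self.cma = CMAFusion(cfg, rng)
        else:
            self.fallback_merge = Conv2d(2 * cfg.enc_channels, cfg.cma_channels,
                                         1, rng)
            self.fallback_rgb = Conv2d(cfg.enc_channels, cfg.cma_channels, 1, rng)
            self.fallback_ir = Conv2d(cfg.enc_channels, cfg.cma_channels, 1, rng)
        self.env_gate = EnvGate(cfg, rng)
        if not cfg.use_reweighting:
            # frozen alpha = 0.5: replace the learnable logit by a constant
            self.env_gate.alpha_logit.requires_grad = False
        self._needs_adapter = (cfg.gate_channels != cfg.cma_channels
                               or cfg.gate_hw != cfg.enc_spatial)
        if self._needs_adapter:
            self.adapter_rgb = Conv2d(cfg.cma_channels, cfg.gate_channels, 1, rng)
            self.adapter_ir = Conv2d(cfg.cma_channels, cfg.gate_channels, 1, rng)
            self.adapter_fused = Conv2d(cfg.cma_channels, cfg.gate_channels, 1, rng)
        head_in = cfg.gate_channels
        self.post_merge = Conv2d(2 * cfg.gate_channels, head_in, 1, rng)
        self.head = DetectionHead(cfg, head_in, rng)
        if cfg.gate_hw % cfg.head_hw:
            raise ValueError("head_hw must divide gate_hw")

    # ------------------------------------------------------------ plumbing
    def _adapt(self, x: Tensor, which: str) -> Tensor:
        """Map a C'xHxW visual stream into the gate's C x gate_hw domain."""
        if self._needs_adapter:
            x = getattr(self, f"adapter_{which}")(x)
            x = adaptive_avg_pool2d(x, (self.cfg.gate_hw, self.cfg.gate_hw))
        return x

    def encode_visual(self, rgb: np.ndarray, thermal: np.ndarray | None
                      ) -> tuple[FeatureMap, FeatureMap]:
        f_rgb = self.rgb_encoder(rgb)
        if "thermal" in self.cfg.modalities:
            if thermal is None:
                raise ValueError("this checkpoint expects a thermal stream; "
                                 "train a modality-subset model to drop it")
            f_ir = self.thermal_encoder(thermal)
        else:
            n = f_rgb.tensor.shape[0]
            stub = self.thermal_stub.reshape(1, *self.thermal_stub.shape)
            tiled = concat([stub] * n, axis=0) if n > 1 else stub
            f_ir = FeatureMap(tiled, "thermal")
        return f_rgb, f_ir

    def env_history_embeddings(self, env_hist: np.ndarray) -> Tensor:
        """(N, T, 3) normalized env histories -> (N, T, width) embeddings."""
        if "sensor" not in self.cfg.modalities:
            n = np.asarray(env_hist).shape[0] if env_hist is not None else 1
            stub = self.env_stub.reshape(1, 1, 3)
            rows = concat([stub] * n, axis=0) if n > 1 else stub
            return self.env_encoder(rows)
        return self.env_encoder(np.asarray(env_hist, dtype=np.float64))

    # ------------------------------------------------------------- forward
    def forward(self, rgb: np.ndarray, thermal: np.ndarray | None,
                env_hist: np.ndarray | None, with_aux: bool = False):
        f_rgb, f_ir = self.encode_visual(rgb, thermal)

        if self.cfg.use_cma:
            fused_cma, stream_rgb, stream_ir = self.cma(f_rgb, f_ir)
            fused_cma = fused_cma.tensor
        else:
            fused_cma = self.fallback_merge(
                concat([f_rgb.tensor, f_ir.tensor], axis=1))
            stream_rgb = self.fallback_rgb(f_rgb.tensor)
            stream_ir = self.fallback_ir(f_ir.tensor)

        a_rgb = self._adapt(stream_rgb, "rgb")
        a_ir = self._adapt(stream_ir, "ir")
        alpha = self.env_gate.alpha if self.cfg.use_reweighting else Tensor(0.5)
        if self.cfg.use_ema:
            emb = self.env_history_embeddings(env_hist)
            gate = self.env_gate.build_gate(emb)
        else:
            gate = Tensor(np.ones((a_rgb.shape[0], self.cfg.gate_channels,
                                   self.cfg.gate_hw, self.cfg.gate_hw)))
        gated = fuse(a_rgb, a_ir, gate, alpha)

        head_in = self.post_merge(concat([self._adapt(fused_cma, "fused"),
                                          gated], axis=1))
        if self.cfg.head_hw != self.cfg.gate_hw:
            head_in = adaptive_avg_pool2d(head_in,
                                          (self.cfg.head_hw, self.cfg.head_hw))
        return self.head(head_in, with_aux=with_aux)

    def last_gate(self, env_hist: np.ndarray | None) -> np.ndarray:
        """The modulation gate the model would apply (ones when EMA is off)."""
        if not self.cfg.use_ema:
            return np.ones((1, self.cfg.gate_channels, self.cfg.gate_hw,
                            self.cfg.gate_hw))
        with no_grad():
            emb = self.env_history_embeddings(env_hist)
            return self.env_gate.build_gate(emb).data


def save_checkpoint(path: str | Path, model: PestPredatorDetector,
                    run_config: RunConfig, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint: weights + config hash + run config."""
    import json
    state = model.state_dict()
    meta = {"config": run_config.to_dict(), "config_hash": run_config.config_hash(),
            **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8),
        **{k: v for k, v in state.items()})


def load_checkpoint(path: str | Path) -> tuple[PestPredatorDetector, RunConfig, dict]:
    import json
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        state = {k: payload[k] for k in payload.files if k != "__meta__"}
    run_config = RunConfig.from_dict(meta["config"])
    model = PestPredatorDetector(run_config.model, seed=run_config.seed)
    model.load_state_dict(state)
    return model, run_config, meta
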