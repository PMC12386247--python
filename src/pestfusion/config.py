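"""Run configuration: model dimensions, loss weights, ablation switches.

Defaults are the published operating point of the architecture
(64-channel 64x64 visual features, 32-channel fused map, 32x32x64
modulation gate, d_model=256 transformer with 6+6 layers and 100
queries per branch).  ``ModelConfig.tiny()`` is the mandatory reduced
configuration used throughout the test-suite and the desk-scale
training experiment: every shape constant shrinks so a CPU can train
the full pipeline in minutes, and the visual/gate shapes coincide so
the shape adapter between the fusion stages becomes the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainConfig", "DataConfig", "RunConfig"]

ALL_MODALITIES = ("rgb", "thermal", "sensor")


@dataclass
class ModelConfig:
    # modality encoders
    enc_channels: int = 64      # C of the intermediate visual features
    enc_spatial: int = 64       # H = W of the intermediate visual features
    enc_depth: int = 3          # conv blocks per visual encoder
    env_width: int = 64         # width of the environmental embedding
    # cross-modal attention fusion
    cma_channels: int = 32      # C' after the 1x1 reduction
    cma_bins: int = 16          # histogram bins for density estimation
    cma_tau: float = 1.0        # KL -> weight temperature, w = exp(-KL/tau)
    cma_grid: int = 8           # local-region grid for the KL field
    # environment-guided modality attention
    ema_depth: int = 3          # state-space stack depth L
    ema_history: int = 8        # env vectors fed to the SSM (1 Hz, pre-frame)
    gate_hw: int = 32           # H = W of the modulation gate
    gate_channels: int = 64     # C of the modulation gate
    # detection head
    head_hw: int = 0            # token grid side for the head; 0 = gate_hw
    d_model: int = 256
    n_heads: int = 8
    enc_layers: int = 6
    dec_layers: int = 6
    ffn_dim: int = 1024
    n_queries: int = 100
    n_classes: int = 8
    aux_loss: bool = True       # deep supervision on every decoder layer
    # loss weights
    lambda_cls: float = 1.0
    lambda_bbox: float = 5.0
    lambda_giou: float = 2.0
    mu_contrastive: float = 0.5
    tau_contrastive: float = 0.1
    no_object_weight: float = 0.1
    # ablation switches
    use_cma: bool = True
    use_ema: bool = True
    use_reweighting: bool = True
    decoupled_head: bool = True
    modalities: tuple[str, ...] = ALL_MODALITIES

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        if "rgb" not in self.modalities:
            raise ValueError("the RGB modality is always retained")
        for m in self.modalities:
            if m not in ALL_MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.head_hw == 0:
            self.head_hw = self.gate_hw

    @property
    def input_size(self) -> int:
        """Canonical image side the visual encoders consume."""
        return self.enc_spatial * 4

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Reduced configuration for CPU-scale tests and experiments."""
        base = dict(
            enc_channels=16, enc_spatial=16, env_width=64,
            cma_channels=8, cma_grid=4,
            gate_hw=16, gate_channels=8, ema_history=4,
            head_hw=8, d_model=64, n_heads=4, enc_layers=2, dec_layers=2,
            ffn_dim=128, n_queries=12)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 4
    steps: int = 500
    warmup_steps: int = 50           # linear warmup, then cosine decay
    min_lr_frac: float = 0.05        # floor of the cosine schedule
    grad_clip: float = 1.0
    sigma_brightness: float = 0.05   # augmentation noise std on [0,1] images
    p_occlusion: float = 0.3         # probability of occlusion augmentation
    augment: bool = True


@dataclass
class DataConfig:
    n_train: int = 64
    n_val: int = 16
    image_size: int = 256
    n_targets: int = 3
    class_distribution: tuple[float, ...] = tuple([1.0 / 8] * 8)
    env_duration: float = 20.0

    def __post_init__(self):
        self.class_distribution = tuple(self.class_distribution)


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(model=ModelConfig(**d.get("model", {})),
                   train=TrainConfig(**d.get("train", {})),
                   data=DataConfig(**d.get("data", {})),
                   seed=int(d.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        payload = self.to_dict()
        payload["model"]["modalities"] = list(payload["model"]["modalities"])
        payload["data"]["class_distribution"] = list(payload["data"]["class_distribution"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
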