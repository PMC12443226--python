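"""Configuration dataclasses and YAML loading.

Two bundled profiles:

* ``full_scale`` — the full-scale layout (224x224 inputs, patch 4, widths
  96/192/384/768, depths 2/2/9/2) and its full-scale optimizer settings.
* ``tiny``       — a CPU-scale profile (32x32 inputs, widths 8/16/32/64,
  depths 1/1/1/1) used by the test-suite and the worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

GROUPINGS = ("four_class", "twelve_class", "binary")


@dataclass(frozen=True)
class BackboneConfig:
    input_size: int = 224
    patch_size: int = 4
    dims: tuple = (96, 192, 384, 768)
    depths: tuple = (2, 2, 9, 2)
    ffn_ratio: float = 4.0
    sa_kernel: int = 7
    ca_ratio: int = 16
    state_dim: int = 8
    norm_mean: tuple = IMAGENET_MEAN
    norm_std: tuple = IMAGENET_STD


@dataclass(frozen=True)
class MetricHeadConfig:
    init_seed: int = 0
    temperature: float | None = None  # cosine logits used raw by default


@dataclass(frozen=True)
class FusionConfig:
    heads: int = 4
    ffn_ratio: float = 4.0
    guidance_mode: str = "hard"  # hard | soft | off
    tokens_per_scale: int = 1  # reserved; only 1 is implemented


@dataclass(frozen=True)
class StagePlan:
    stage: int
    epochs: int
    batch_size: int
    learning_rate: float
    optimizer: str = "adam"
    augment: bool = True


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    metric_head: MetricHeadConfig = field(default_factory=MetricHeadConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    grouping: str = "four_class"
    stage1: StagePlan = field(
        default_factory=lambda: StagePlan(stage=1, epochs=50, batch_size=96, learning_rate=1e-4)
    )
    stage2: StagePlan = field(
        default_factory=lambda: StagePlan(stage=2, epochs=100, batch_size=512, learning_rate=1e-4)
    )

    def to_dict(self) -> dict:
        return asdict(self)


def full_scale_config() -> ModelConfig:
    return ModelConfig()


def tiny_config(guidance_mode: str = "hard", grouping: str = "four_class") -> ModelConfig:
    """CPU-scale profile used throughout the tests and examples."""
    return ModelConfig(
        backbone=BackboneConfig(
            input_size=32,
            dims=(8, 16, 32, 64),
            depths=(1, 1, 1, 1),
            ffn_ratio=2.0,
            ca_ratio=4,
            state_dim=4,
        ),
        fusion=FusionConfig(guidance_mode=guidance_mode),
        grouping=grouping,
        stage1=StagePlan(stage=1, epochs=50, batch_size=32, learning_rate=3e-3),
        stage2=StagePlan(stage=2, epochs=300, batch_size=512, learning_rate=3e-3, augment=False),
    )


def micro_config(guidance_mode: str = "hard", grouping: str = "four_class") -> ModelConfig:
    """Smallest runnable profile; exercises machinery, not accuracy."""
    cfg = tiny_config(guidance_mode=guidance_mode, grouping=grouping)
    return replace(
        cfg,
        stage1=StagePlan(stage=1, epochs=4, batch_size=32, learning_rate=3e-3),
        stage2=StagePlan(stage=2, epochs=60, batch_size=512, learning_rate=3e-3, augment=False),
    )


def _merge(cfg, overrides: dict):
    kwargs = {}
    for key, val in overrides.items():
        cur = getattr(cfg, key)
        if hasattr(cur, "__dataclass_fields__") and isinstance(val, dict):
            kwargs[key] = _merge(cur, val)
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return replace(cfg, **kwargs)


def load_config(path, base: str = "full_scale") -> ModelConfig:
    """Load a YAML file of overrides on top of a named base profile."""
    cfg = tiny_config() if base == "tiny" else full_scale_config()
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if "base" in overrides:
        base = overrides.pop("base")
        cfg = tiny_config() if base == "tiny" else full_scale_config()
    return _merge(cfg, overrides)
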