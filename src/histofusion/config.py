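"""Model configuration: dataclasses, presets, and YAML round-trip.

Two presets are provided.  ``full`` is the full-scale architecture
(50-layer bottleneck CNN with 2048 output channels, 12-layer ViT with
dimension 768 and CLS taps at layers 6/9/12, 768-dimensional fusion with
8 heads).  ``reduced`` keeps every structural property — five CNN stages with
total stride 32, three evenly spaced CLS taps ending at the final layer,
two-stage fusion attention — at a width that trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class BackboneConfig:
    """Residual CNN branch (five stages, total stride 32)."""

    stem_channels: int = 64
    stage_channels: tuple = (256, 512, 1024, 2048)  # bottleneck outputs
    stage_blocks: tuple = (3, 4, 6, 3)
    se_reduction: int = 16          # SE bottleneck ratio r
    embed_dim: int = 768            # projection target d
    use_se: bool = True
    input_mean: tuple = (0.5, 0.5, 0.5)
    input_std: tuple = (0.5, 0.5, 0.5)

    @property
    def out_channels(self) -> int:
        return self.stage_channels[-1]

    @property
    def total_stride(self) -> int:
        return 32


@dataclass
class VitConfig:
    patch_size: int = 16
    dim: int = 768
    depth: int = 12
    heads: int = 12
    mlp_ratio: float = 4.0
    tap_layers: tuple = (6, 9, 12)  # 1-based encoder blocks whose CLS is tapped


@dataclass
class FusionConfig:
    dim: int = 768
    heads: int = 8
    mhsa_blocks: int = 1
    ta_blocks: int = 1
    sequence_mode: str = "tokens3"  # "tokens3" | "single" (strict T=1 reading)
    dropout: float = 0.5
    residual: bool = True
    use_tama: bool = True           # False: classify straight off the joint token


@dataclass
class ModelConfig:
    n_classes: int = 4
    cnn: BackboneConfig = field(default_factory=BackboneConfig)
    vit: VitConfig = field(default_factory=VitConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    branches: str = "dual"          # "dual" | "cnn" | "vit" (ablation arms)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        cnn = BackboneConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d.pop("cnn", {}).items()})
        vit = VitConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.pop("vit", {}).items()})
        fusion = FusionConfig(**d.pop("fusion", {}))
        return cls(cnn=cnn, vit=vit, fusion=fusion, **d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw.get("model", raw))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.to_dict()}, fh)


def full_config(n_classes: int = 4) -> ModelConfig:
    return ModelConfig(n_classes=n_classes)


def reduced_config(n_classes: int = 4, dim: int = 64) -> ModelConfig:
    """CPU-scale configuration preserving the full model's structure."""
    return ModelConfig(
        n_classes=n_classes,
        cnn=BackboneConfig(stem_channels=8, stage_channels=(16, 32, 64, 128),
                           stage_blocks=(1, 1, 1, 1), se_reduction=4,
                           embed_dim=dim),
        vit=VitConfig(patch_size=12, dim=dim, depth=4, heads=4,
                      mlp_ratio=2.0, tap_layers=(2, 3, 4)),
        fusion=FusionConfig(dim=dim, heads=4, dropout=0.1),
    )
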