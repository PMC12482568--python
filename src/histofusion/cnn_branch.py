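"""Residual CNN branch with squeeze-and-excitation channel recalibration.

The branch is a five-stage residual network (stem + four bottleneck stages,
total stride 32).  After the final stage one SE block recalibrates channels:
the feature map is globally average-pooled into a per-channel descriptor,
passed through a two-layer bottleneck MLP (reduction ratio ``r``), and the
sigmoid output rescales each channel,

    s = sigmoid(W2 relu(W1 GAP(F))),    F~ = F (.) s.

The recalibrated map is pooled again and linearly projected into the shared
embedding space of dimension ``d`` so it can be fused with the transformer
branch.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import BackboneConfig


class ShapeError(ValueError):
    pass


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 residual block with expansion built into widths."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        mid = max(out_ch // 4, 4)
        self.conv1 = nn.Conv2d(in_ch, mid, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1,
                               bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + self.down(x)).relu()


class SEGate(nn.Module):
    """Squeeze-and-excitation gate; ``forward`` returns per-channel weights
    in the open interval (0, 1)."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)
        # start at the neutral gate sigma(0)=0.5: keeps weights in the
        # sigmoid's responsive range regardless of descriptor magnitude
        self.fc2.weight.data[:] = 0.0

    def forward(self, features: nn.Tensor) -> nn.Tensor:
        descriptor = features.mean(axis=(2, 3))            # GAP -> (B, C)
        return self.fc2(self.fc1(descriptor).relu()).sigmoid()


def se_recalibrate(features: nn.Tensor, gate: SEGate,
                   bypass: bool = False):
    """Rescale each channel of ``features`` by its SE gate weight.

    Returns ``(recalibrated, weights)`` where ``weights`` is the (B, C) gate
    output.  With ``bypass=True`` the gate is forced to all-ones, which makes
    the operation an exact identity (the no-SE baseline).
    """
    if bypass:
        ones = np.ones(features.shape[:2], np.float32)
        return features, ones
    s = gate(features)
    expected = features.shape[1]
    if s.shape[1] != expected:
        raise ShapeError(f"gate produced {s.shape[1]} weights for "
                         f"{expected} channels")
    B, C = s.shape
    return features * s.reshape(B, C, 1, 1), s.data


class ResNetBackbone(nn.Module):
    """Stem (7x7 conv, stride 2, 3x3 max-pool stride 2) + four bottleneck
    stages with strides (1, 2, 2, 2); total stride 32 at every scale."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        c = config.stem_channels
        self.stem_conv = nn.Conv2d(3, c, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(c)
        self.stem_pool = nn.MaxPool2d(3, stride=2, padding=1)
        in_ch = c
        for i, (out_ch, blocks) in enumerate(
                zip(config.stage_channels, config.stage_blocks), start=1):
            stride = 1 if i == 1 else 2
            mods = []
            for b in range(blocks):
                mods.append(Bottleneck(in_ch, out_ch,
                                       stride if b == 0 else 1))
                in_ch = out_ch
            setattr(self, f"stage{i}", nn.Sequential(*mods))
        # populated on forward(record=True); used by Grad-CAM
        self.activations: dict[str, nn.Tensor] = {}

    def forward(self, x: nn.Tensor, record: bool = False) -> nn.Tensor:
        stride = self.config.total_stride
        H, W = x.shape[2], x.shape[3]
        if H % stride or W % stride:
            raise ShapeError(
                f"input spatial dims {H}x{W} must be divisible by the "
                f"backbone's total stride {stride}")
        if record:
            self.activations = {}
        out = self.stem_pool(self.stem_bn(self.stem_conv(x)).relu())
        for i in (1, 2, 3, 4):
            stage = getattr(self, f"stage{i}")
            for b, block in enumerate(stage):
                out = block(out)
                if record:
                    self.activations[f"stage{i}.block{b}"] = out
        return out

    def layer_names(self) -> list[str]:
        names = []
        for i in (1, 2, 3, 4):
            for b in range(len(list(getattr(self, f"stage{i}")))):
                names.append(f"stage{i}.block{b}")
        return names


class CNNBranch(nn.Module):
    """Backbone -> SE recalibration -> GAP -> linear projection to d."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        self.backbone = ResNetBackbone(config)
        self.se = SEGate(config.out_channels, config.se_reduction)
        self.proj = nn.Linear(config.out_channels, config.embed_dim)
        self.last_gate: np.ndarray | None = None

    def extract_local_features(self, images: nn.Tensor,
                               record: bool = False) -> nn.Tensor:
        return self.backbone(images, record=record)

    def project_embedding(self, features: nn.Tensor) -> nn.Tensor:
        return self.proj(features.mean(axis=(2, 3)))

    def forward(self, images: nn.Tensor, record: bool = False) -> nn.Tensor:
        feats = self.extract_local_features(images, record=record)
        recal, gate = se_recalibrate(feats, self.se,
                                     bypass=not self.config.use_se)
        self.last_gate = gate
        return self.project_embedding(recal)


def extract_local_features(images: nn.Tensor,
                           config: BackboneConfig) -> nn.Tensor:
    """Functional form: build a randomly initialized backbone from ``config``
    and run it.  Mostly useful for shape-contract checks; persistent models
    should construct :class:`CNNBranch` once."""
    return ResNetBackbone(config)(images)


def project_cnn_embedding(features: nn.Tensor, proj: nn.Linear) -> nn.Tensor:
    """Spatial mean followed by the linear map W_cnn (+ bias)."""
    if proj.weight.shape[0] != features.shape[1]:
        raise ShapeError(
            f"projection expects {proj.weight.shape[0]} channels, feature "
            f"map has {features.shape[1]}")
    return proj(features.mean(axis=(2, 3)))
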