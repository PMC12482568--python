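"""Vision Transformer branch with multi-depth [CLS] taps.

The image is cut into non-overlapping P x P patches, each flattened and
linearly projected to a D-dimensional token; a learnable [CLS] token is
prepended and a learnable position encoding added once.  The sequence runs
through a stack of pre-norm transformer encoder blocks.  Instead of reading
only the final [CLS] state, the branch captures the [CLS] vector after each
configured tap layer (default layers 6, 9, 12 of a 12-deep encoder) and
averages them, blending mid-level and high-level global context:

    z_vit = mean_l in taps  cls^(l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cnn_branch import ShapeError
from .config import VitConfig


@dataclass
class ClsTap:
    layer_index: int          # 1-based encoder block index
    vector: nn.Tensor         # (B, D)


class PatchEmbed(nn.Module):
    def __init__(self, patch_size: int, dim: int):
        super().__init__()
        self.patch_size = patch_size
        self.proj = nn.Linear(3 * patch_size * patch_size, dim)

    def forward(self, images: nn.Tensor) -> nn.Tensor:
        """(B, 3, H, W) -> patch tokens (B, N, D), N = (H/P)(W/P)."""
        P = self.patch_size
        B, C, H, W = images.shape
        if H % P or W % P:
            raise ShapeError(f"image dims {H}x{W} not divisible by patch "
                             f"size {P}")
        nh, nw = H // P, W // P
        x = images.reshape(B, C, nh, P, nw, P)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(B, nh * nw, C * P * P)
        return self.proj(x)


class EncoderBlock(nn.Module):
    """Pre-norm transformer block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float):
        super().__init__()
        self.heads = heads
        self.norm1 = nn.LayerNorm(dim)
        self.wq = nn.Linear(dim, dim)
        self.wk = nn.Linear(dim, dim)
        self.wv = nn.Linear(dim, dim)
        self.wo = nn.Linear(dim, dim)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.mlp1 = nn.Linear(dim, hidden)
        self.mlp2 = nn.Linear(hidden, dim)
        # residual branches start near zero so a freshly initialized deep
        # encoder is close to the identity (helps small-data training)
        self.wo.weight.data *= 0.1
        self.mlp2.weight.data *= 0.1
        self.last_attention: np.ndarray | None = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.norm1(x)
        attended, weights = nn.multi_head_attention(
            self.wq(h), self.wk(h), self.wv(h), self.heads,
            return_weights=True)
        self.last_attention = weights
        x = x + self.wo(attended)
        return x + self.mlp2(self.mlp1(self.norm2(x)).gelu())


class ViTBranch(nn.Module):
    def __init__(self, config: VitConfig, image_size: int):
        super().__init__()
        self.config = config
        if any(t < 1 or t > config.depth for t in config.tap_layers):
            raise ValueError(
                f"tap layers {config.tap_layers} outside encoder depth "
                f"{config.depth}")
        self.patch_embed = PatchEmbed(config.patch_size, config.dim)
        n_patches = (image_size // config.patch_size) ** 2
        rng = np.random.default_rng(0)
        self.cls_token = nn.Tensor(
            rng.normal(0, 0.02, (1, 1, config.dim)).astype(np.float32),
            requires_grad=True)
        self.pos_embed = nn.Tensor(
            rng.normal(0, 0.02,
                       (1, n_patches + 1, config.dim)).astype(np.float32),
            requires_grad=True)
        for i in range(config.depth):
            setattr(self, f"block{i}",
                    EncoderBlock(config.dim, config.heads, config.mlp_ratio))

    def embed(self, images: nn.Tensor) -> nn.Tensor:
        """Patch tokens + prepended [CLS] + position encoding (added once)."""
        tokens = self.patch_embed(images)                    # (B, N, D)
        B = tokens.shape[0]
        cls = self.cls_token * nn.Tensor(np.ones((B, 1, 1), np.float32))
        seq = nn.concat([cls, tokens], axis=1)
        if seq.shape[1] != self.pos_embed.shape[1]:
            raise ShapeError(
                f"sequence length {seq.shape[1]} does not match position "
                f"encoding length {self.pos_embed.shape[1]}")
        return seq + self.pos_embed

    def encode_with_cls_taps(self, seq: nn.Tensor,
                             tap_layers=None) -> list[ClsTap]:
        """Run the encoder, capturing the [CLS] state after each tap layer
        (post-residual block output).  Taps are returned in ascending order."""
        taps_wanted = sorted(tap_layers or self.config.tap_layers)
        if not taps_wanted:
            raise ValueError("need at least one tap layer")
        if any(t < 1 or t > self.config.depth for t in taps_wanted):
            raise ValueError(f"tap layers {taps_wanted} outside depth "
                             f"{self.config.depth}")
        taps = []
        x = seq
        for i in range(self.config.depth):
            x = getattr(self, f"block{i}")(x)
            if (i + 1) in taps_wanted:
                taps.append(ClsTap(layer_index=i + 1, vector=x[:, 0, :]))
        return taps

    def forward(self, images: nn.Tensor) -> nn.Tensor:
        return fuse_cls_tokens(self.encode_with_cls_taps(self.embed(images)))


def fuse_cls_tokens(taps: list[ClsTap]) -> nn.Tensor:
    """Arithmetic mean of the tapped [CLS] vectors."""
    if not taps:
        raise ValueError("cannot fuse an empty tap list")
    out = taps[0].vector
    for t in taps[1:]:
        out = out + t.vector
    return out * (1.0 / len(taps))
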