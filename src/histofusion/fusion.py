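"""Token-aligned multimodal attention (TAMA) fusion and the full classifier.

The CNN embedding and the ViT embedding (both d-dimensional) are turned into
a short fusion token sequence: the two branch tokens plus a joint token
obtained by concatenating them and linearly projecting 2d -> d.  The sequence
passes through a two-stage attention unit — a multi-head self-attention stage
(8 heads at full scale) followed by a token-alignment (TA) layer consisting
of LayerNorm, a shared Q/K/V projection, multi-head attention, and an output
projection — and is mean-pooled into the fused representation, which a
ReLU + dropout + linear head maps to class probabilities.

A strict single-token reading (the joint token alone, T = 1) is available via
``sequence_mode="single"``; self-attention over one token is the identity up
to the value/output projections.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .cnn_branch import CNNBranch, ShapeError
from .config import ModelConfig
from .vit_branch import ViTBranch


def align_tokens(z_cnn: nn.Tensor, z_vit: nn.Tensor, proj: nn.Linear,
                 mode: str = "tokens3") -> nn.Tensor:
    """Build the fusion token sequence (B, T, d).

    ``tokens3``: [z_cnn, z_vit, proj([z_cnn; z_vit])].  ``single``: the
    projected joint token only.
    """
    if z_cnn.shape != z_vit.shape:
        raise ShapeError(f"branch embeddings disagree: {z_cnn.shape} vs "
                         f"{z_vit.shape}")
    B, d = z_cnn.shape
    joint = proj(nn.concat([z_cnn, z_vit], axis=1))        # (B, d)
    if mode == "single":
        return joint.reshape(B, 1, d)
    if mode != "tokens3":
        raise ValueError(f"unknown sequence mode: {mode!r}")
    return nn.concat([z_cnn.reshape(B, 1, d), z_vit.reshape(B, 1, d),
                      joint.reshape(B, 1, d)], axis=1)


class MHSAStage(nn.Module):
    """First fusion stage: multi-head self-attention with separate Q/K/V
    projections and a residual connection."""

    def __init__(self, dim: int, heads: int, residual: bool = True):
        super().__init__()
        self.heads, self.residual = heads, residual
        self.wq = nn.Linear(dim, dim)
        self.wk = nn.Linear(dim, dim)
        self.wv = nn.Linear(dim, dim)
        self.wo = nn.Linear(dim, dim)
        if residual:  # zero-init residual projection: stage starts as identity
            self.wo.weight.data[:] = 0.0
        self.last_attention: np.ndarray | None = None

    def forward(self, seq: nn.Tensor) -> nn.Tensor:
        out, w = nn.multi_head_attention(
            self.wq(seq), self.wk(seq), self.wv(seq), self.heads,
            return_weights=True)
        self.last_attention = w
        out = self.wo(out)
        return seq + out if self.residual else out


class TALayer(nn.Module):
    """Second fusion stage: LayerNorm -> shared Q/K/V projection ->
    multi-head attention -> output projection, wrapped pre-norm residual.

    With the output projection zeroed and the residual enabled the layer is
    an exact identity map.
    """

    def __init__(self, dim: int, heads: int, residual: bool = True):
        super().__init__()
        self.heads, self.residual = heads, residual
        self.norm = nn.LayerNorm(dim)
        self.shared_qkv = nn.Linear(dim, dim)   # one projection for Q, K, V
        self.wo = nn.Linear(dim, dim)
        if residual:
            self.wo.weight.data[:] = 0.0
        self.last_attention: np.ndarray | None = None

    def forward(self, seq: nn.Tensor) -> nn.Tensor:
        h = self.norm(seq)
        qkv = self.shared_qkv(h)
        out, w = nn.multi_head_attention(qkv, qkv, qkv, self.heads,
                                         return_weights=True)
        self.last_attention = w
        out = self.wo(out)
        return seq + out if self.residual else out


class ClassifierHead(nn.Module):
    """phi = ReLU + dropout, then the linear map to C logits."""

    def __init__(self, dim: int, n_classes: int, dropout: float):
        super().__init__()
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.drop = nn.Dropout(dropout)
        self.fc = nn.Linear(dim, n_classes)

    def forward(self, pooled: nn.Tensor) -> nn.Tensor:
        return self.fc(self.drop(pooled.relu()))


def pool_and_classify(seq: nn.Tensor, head: ClassifierHead) -> nn.Tensor:
    """Mean over the T fusion tokens, then the head; rows on the simplex."""
    return nn.softmax(head(seq.mean(axis=1)), axis=-1)


class HistoFusionNet(nn.Module):
    """Parallel CNN + ViT classifier with TAMA fusion.

    ``config.branches`` selects the ablation arm: ``dual`` (full model),
    ``cnn`` or ``vit`` (single branch feeding the head directly).  With
    ``config.fusion.use_tama`` false the head classifies the projected joint
    token without either attention stage (the plain concat+projection arm).
    """

    def __init__(self, config: ModelConfig, image_size: int):
        super().__init__()
        if config.fusion.dim % config.fusion.heads:
            raise ValueError(
                f"fusion dim {config.fusion.dim} not divisible by "
                f"{config.fusion.heads} heads")
        self.config = config
        self.image_size = image_size
        fc = config.fusion
        if config.branches in ("dual", "cnn"):
            self.cnn = CNNBranch(config.cnn)
        if config.branches in ("dual", "vit"):
            self.vit = ViTBranch(config.vit, image_size)
        if config.branches == "dual":
            self.align_proj = nn.Linear(2 * fc.dim, fc.dim)
            self.mhsa_stages = nn.Sequential(*[
                MHSAStage(fc.dim, fc.heads, fc.residual)
                for _ in range(fc.mhsa_blocks)])
            self.ta_stages = nn.Sequential(*[
                TALayer(fc.dim, fc.heads, fc.residual)
                for _ in range(fc.ta_blocks)])
        self.head = ClassifierHead(fc.dim, config.n_classes, fc.dropout)
        self._norm_mean = np.asarray(config.cnn.input_mean,
                                     np.float32).reshape(1, 3, 1, 1)
        self._norm_std = np.asarray(config.cnn.input_std,
                                    np.float32).reshape(1, 3, 1, 1)

    # ------------------------------------------------------------------
    def _prepare(self, images) -> nn.Tensor:
        if not isinstance(images, nn.Tensor):
            images = nn.Tensor(np.asarray(images, np.float32))
        return (images - nn.Tensor(self._norm_mean)) \
            * nn.Tensor(1.0 / self._norm_std)

    def fused_sequence(self, images, record_cams: bool = False) -> nn.Tensor:
        x = self._prepare(images)
        z_cnn = self.cnn(x, record=record_cams)
        z_vit = self.vit(x)
        seq = align_tokens(z_cnn, z_vit, self.align_proj,
                           self.config.fusion.sequence_mode)
        if self.config.fusion.use_tama:
            seq = self.ta_stages(self.mhsa_stages(seq))
        return seq

    def logits(self, images, record_cams: bool = False) -> nn.Tensor:
        if self.config.branches == "cnn":
            x = self._prepare(images)
            return self.head(self.cnn(x, record=record_cams))
        if self.config.branches == "vit":
            return self.head(self.vit(self._prepare(images)))
        seq = self.fused_sequence(images, record_cams=record_cams)
        return self.head(seq.mean(axis=1))

    def fused_representation(self, images) -> np.ndarray:
        """Mean-pooled TA-layer output, shape (B, d)."""
        return self.fused_sequence(images).mean(axis=1).data

    def forward(self, images, record_cams: bool = False) -> nn.Tensor:
        """Class probabilities (B, C); deterministic in eval mode."""
        return nn.softmax(self.logits(images, record_cams=record_cams),
                          axis=-1)

    # ------------------------------------------------------------------
    def cam_layer_names(self) -> list[str]:
        return self.cnn.backbone.layer_names()

    def default_cam_layers(self) -> list[str]:
        """Three representative CNN layers for fused Grad-CAM.

        At full scale: the stage-3 final block, the stage-4 second block and
        the stage-4 final block.  When stage 4 has a single block (reduced
        scale), the stage-2 final block substitutes so the fusion still
        averages three maps at three spatial resolutions.
        """
        names = self.cam_layer_names()
        s2 = [n for n in names if n.startswith("stage2.")]
        s3 = [n for n in names if n.startswith("stage3.")]
        s4 = [n for n in names if n.startswith("stage4.")]
        if len(s4) > 1:
            return [s3[-1], s4[1], s4[-1]]
        return [s2[-1], s3[-1], s4[-1]]
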