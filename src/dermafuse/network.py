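"""The full multimodal lesion network.

Image -> backbone feature map F -> metadata-conditioned channel gates
(recalibration) -> FiLM modulation + cross-attention fusion -> global
average pooling -> dropout -> linear classifier over the six classes.
"""

from __future__ import annotations

import numpy as np

from .amcr import AmcrConfig, ChannelAttention, MetadataEmbedder, global_average_pool, recalibrate
from .autodiff import Tensor, no_grad
from .backbone import Backbone, BackboneConfig
from .fusion import FusionConfig, MdfmCaf
from .nn import Dropout, Linear, Module

__all__ = ["LesionNet", "ImageOnlyNet", "predict_proba"]


class LesionNet(Module):
    """Multimodal classifier; `use_fusion=False` drops the cross-attention
    stage (recalibration only), `image_only` ignores metadata entirely
    (ablation baseline)."""

    def __init__(self, backbone_cfg: BackboneConfig, amcr_cfg: AmcrConfig,
                 n_classes: int = 6, head_dropout: float = 0.5,
                 use_fusion: bool = True, seed: int = 0):
        super().__init__()
        self.backbone_cfg = backbone_cfg
        self.amcr_cfg = amcr_cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.backbone = Backbone(backbone_cfg)
        C = backbone_cfg.output_channels
        self.embedder = MetadataEmbedder(amcr_cfg, rng)
        self.attention = ChannelAttention(C, amcr_cfg, rng)
        self.use_fusion = use_fusion
        if use_fusion:
            self.fusion = MdfmCaf(FusionConfig(channels=C, embed_dim=amcr_cfg.embed_dim), rng)
        self.head_drop = Dropout(head_dropout)
        self.classifier = Linear(C, n_classes, rng)
        self.last_alpha: np.ndarray | None = None  # most recent channel gates

    def forward(self, I: Tensor, M: Tensor) -> Tensor:
        """(B, 3, S, S), (B, 81) -> logits (B, n_classes)."""
        F = self.backbone(I)
        z = global_average_pool(F)
        e = self.embedder(M)
        alpha = self.attention(z, e)
        self.last_alpha = alpha.data
        F = recalibrate(F, alpha)
        if self.use_fusion:
            F = self.fusion(F, e)
        pooled = global_average_pool(F)
        return self.classifier(self.head_drop(pooled))


class ImageOnlyNet(Module):
    """Image-only ablation: same backbone and head, metadata ignored."""

    def __init__(self, backbone_cfg: BackboneConfig, n_classes: int = 6,
                 head_dropout: float = 0.5, seed: int = 0):
        super().__init__()
        self.backbone_cfg = backbone_cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.backbone = Backbone(backbone_cfg)
        self.head_drop = Dropout(head_dropout)
        self.classifier = Linear(backbone_cfg.output_channels, n_classes, rng)

    def forward(self, I: Tensor, M: Tensor | None = None) -> Tensor:
        pooled = global_average_pool(self.backbone(I))
        return self.classifier(self.head_drop(pooled))


def predict_proba(model: Module, images: np.ndarray, metadata: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    """Deterministic eval-mode softmax scores, (n, n_classes)."""
    was_training = model.training
    model.eval()
    out = []
    try:
        for start in range(0, len(images), batch_size):
            I = Tensor(images[start:start + batch_size])
            M = Tensor(metadata[start:start + batch_size])
            with no_grad():
                logits = model(I, M)
            out.append(logits.softmax(axis=-1).data)
    finally:
        model.train(was_training)
    return np.concatenate(out, axis=0)
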