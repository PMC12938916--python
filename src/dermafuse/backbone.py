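"""Convolutional feature extractor producing the C×H×W map the fusion
modules consume.

Two geometries are supported: ``resnet50``-compatible dimensions (224-pixel
input -> 2048×7×7, the layer4 geometry of a ResNet50) realised as a strided
convolutional stack, and a ``tiny`` three-block variant (32-pixel input ->
64×4×4) whose dims propagate through every downstream config so end-to-end
tests run in seconds.  Output shape is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .datamodel import FeatureMap, LesionImage
from .nn import Conv2d, Dropout, Module, ReLU

__all__ = ["BackboneConfig", "Backbone", "extract_features", "ShapeError"]


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    architecture: str = "tiny"  # "tiny" | "resnet50"
    input_size: int = 32
    feature_dropout: float = 0.0  # optional MC-dropout site on the feature map
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("tiny", "resnet50"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "resnet50" and self.input_size != 224:
            raise ValueError("resnet50 geometry requires 224-pixel input")

    @property
    def output_channels(self) -> int:
        return 2048 if self.architecture == "resnet50" else 64

    @property
    def output_spatial(self) -> int:
        if self.architecture == "resnet50":
            return 7
        return self.input_size // 8  # three stride-2 blocks

    @classmethod
    def tiny(cls, input_size: int = 32, **kw) -> "BackboneConfig":
        return cls(architecture="tiny", input_size=input_size, **kw)

    @classmethod
    def resnet50(cls, **kw) -> "BackboneConfig":
        return cls(architecture="resnet50", input_size=224, **kw)


class Backbone(Module):
    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.architecture == "tiny":
            chans = [3, 16, 32, 64]
            self.blocks = [Conv2d(chans[i], chans[i + 1], 3, stride=2, pad=1, rng=rng)
                           for i in range(3)]
        else:
            # 224 -> 112 -> 56 -> 28 -> 14 -> 7 with the layer4 channel width
            chans = [3, 64, 256, 512, 1024, 2048]
            self.blocks = [Conv2d(chans[i], chans[i + 1], 3, stride=2, pad=1, rng=rng)
                           for i in range(5)]
        self.act = ReLU()
        self.drop = Dropout(cfg.feature_dropout)

    def forward(self, x: Tensor) -> Tensor:
        """(B, 3, S, S) -> (B, C, H, W)."""
        expected = self.cfg.input_size
        if x.shape[1:] != (3, expected, expected):
            raise ShapeError(
                f"expected input (B, 3, {expected}, {expected}), got {x.shape}")
        for block in self.blocks:
            x = self.act(block(x))
        return self.drop(x)


def extract_features(image: LesionImage, cfg: BackboneConfig | Backbone) -> FeatureMap:
    """Run the (deterministic, eval-mode) backbone on one image."""
    backbone = Backbone(cfg) if isinstance(cfg, BackboneConfig) else cfg
    was_training = backbone.training
    backbone.eval()
    try:
        with no_grad():
            out = backbone(Tensor(image.pixels[None]))
    finally:
        backbone.train(was_training)
    return FeatureMap(out.data[0], stage="backbone")
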