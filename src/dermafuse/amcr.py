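"""Metadata-conditioned channel recalibration with Monte-Carlo-dropout
uncertainty.

A squeeze-excite-style gate conditioned on clinical metadata: the feature
map is pooled to a channel descriptor z, the metadata vector is embedded
through a regularised fully connected stage (batch norm, ReLU, dropout
p=0.5), and an MLP over [z; e_M] emits sigmoid channel gates α ∈ (0,1)^C
that rescale the map.  Predictive uncertainty is estimated by keeping
dropout live over T stochastic forward passes and taking the per-class
variance of the softmax outputs; the variance maps to a focal-loss weight
w = 1 / (1 + exp(−λ σ²)), so w = 0.5 at zero variance and grows
monotonically — for softmax outputs σ² ≤ 0.25, hence with λ = 0.1 the
weight lives in [0.5, 1/(1+e^{−0.025})] ≈ [0.5, 0.50625].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .datamodel import FeatureMap
from .nn import BatchNorm1d, Dropout, Linear, Module, mc_dropout_mode, seed_dropout

__all__ = [
    "AmcrConfig",
    "MetadataEmbedder",
    "ChannelAttention",
    "global_average_pool",
    "recalibrate",
    "mc_predictive_variance",
    "uncertainty_weight",
]


@dataclass(frozen=True)
class AmcrConfig:
    metadata_dim: int = 81
    embed_dim: int = 512       # d
    hidden_dim: int = 256      # C' of the attention MLP
    dropout: float = 0.5       # p, the MC-dropout rate
    mc_passes: int = 10        # T
    lam: float = 0.1           # λ, uncertainty->weight sensitivity

    def __post_init__(self):
        if self.mc_passes < 1:
            raise ValueError("mc_passes (T) must be >= 1")


def global_average_pool(F) -> Tensor:
    """Channel descriptor z_c = mean over the H×W grid of channel c.

    Accepts a FeatureMap, a (C, H, W) array or a batched (B, C, H, W)
    Tensor; returns a Tensor of shape (C,) or (B, C).
    """
    if isinstance(F, FeatureMap):
        F = Tensor(F.values)
    elif isinstance(F, np.ndarray):
        F = Tensor(F)
    if F.ndim == 3:
        if F.shape[1] == 0 or F.shape[2] == 0:
            raise ValueError("feature map has empty spatial dims")
        return F.mean(axis=(1, 2))
    if F.ndim == 4:
        if F.shape[2] == 0 or F.shape[3] == 0:
            raise ValueError("feature map has empty spatial dims")
        return F.mean(axis=(2, 3))
    raise ValueError(f"expected 3- or 4-d feature map, got shape {F.shape}")


class MetadataEmbedder(Module):
    """e_M = Dropout(ReLU(BN(W_M · M + b_M)))."""

    def __init__(self, cfg: AmcrConfig, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(cfg.metadata_dim, cfg.embed_dim, rng)
        self.bn = BatchNorm1d(cfg.embed_dim)
        self.drop = Dropout(cfg.dropout)

    def forward(self, M: Tensor) -> Tensor:
        return self.drop(self.bn(self.fc(M)).relu())


class ChannelAttention(Module):
    """α = sigmoid(W2 · ReLU(W1 · [z; e_M] + b1) + b2) ∈ (0, 1)^C."""

    def __init__(self, channels: int, cfg: AmcrConfig, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(channels + cfg.embed_dim, cfg.hidden_dim, rng)
        self.fc2 = Linear(cfg.hidden_dim, channels, rng)

    def forward(self, z: Tensor, e_M: Tensor) -> Tensor:
        joint = concat([z, e_M], axis=-1)
        return self.fc2(self.fc1(joint).relu()).sigmoid()


def recalibrate(F: Tensor | FeatureMap, alpha: Tensor | np.ndarray):
    """F'_c = α_c · F_c (channel gates broadcast over the spatial grid)."""
    as_map = isinstance(F, FeatureMap)
    stageless = F.values if as_map else F
    x = Tensor(stageless) if isinstance(stageless, np.ndarray) else stageless
    a = alpha if isinstance(alpha, Tensor) else Tensor(np.asarray(alpha))
    C = x.shape[-3]
    if a.shape[-1] != C:
        raise ValueError(f"gate length {a.shape[-1]} != channel count {C}")
    if x.ndim == 3:
        out = x * a.reshape(C, 1, 1)
    else:
        out = x * a.reshape(a.shape[0], C, 1, 1)
    if as_map:
        return FeatureMap(out.data, stage="recalibrated")
    return out


def mc_predictive_variance(model, image: np.ndarray, metadata: np.ndarray,
                           T: int = 10, seed: int = 0,
                           population: bool = True) -> np.ndarray:
    """Per-class variance of softmax outputs over T stochastic passes.

    Dropout stays live while batch-norm statistics are frozen, so dropout is
    the only source of stochasticity.  Population variance (divisor T) by
    default; set ``population=False`` for the sample variance.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    probs = mc_softmax_samples(model, image, metadata, T, seed)
    ddof = 0 if population else 1
    if T == 1:
        return np.zeros(probs.shape[1])
    return probs.var(axis=0, ddof=ddof)


def mc_softmax_samples(model, image: np.ndarray, metadata: np.ndarray,
                       T: int, seed: int = 0) -> np.ndarray:
    """(T, n_classes) softmax draws under Monte-Carlo dropout."""
    image = np.asarray(image)
    metadata = np.asarray(metadata)
    if image.ndim == 3:
        image = image[None]
    if metadata.ndim == 1:
        metadata = metadata[None]
    out = []
    with mc_dropout_mode(model):
        seed_dropout(model, seed)
        for _ in range(T):
            with no_grad():
                logits = model(Tensor(image), Tensor(metadata))
            out.append(logits.softmax(axis=-1).data[0])
    return np.stack(out)


def uncertainty_weight(variance, lam: float = 0.1):
    """w = 1 / (1 + exp(−λ σ²)); 0.5 at σ² = 0, strictly increasing."""
    variance = np.asarray(variance, dtype=np.float64)
    if np.any(variance < 0):
        raise ValueError("variance must be >= 0")
    w = 1.0 / (1.0 + np.exp(-lam * variance))
    return float(w) if w.ndim == 0 else w
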