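"""Metadata-driven feature modulation and cross-attention fusion.

Stage one is FiLM-style conditioning: the metadata embedding predicts a
per-channel affine transform (γ, β) applied to the recalibrated feature
map.  Stage two treats the H×W spatial positions as tokens (row-major
flattening, N = H·W), projects them to queries/keys/values with square
per-token maps, adds a metadata-derived key vector K_M to every key row,
and applies single-head scaled dot-product attention (scale √C) followed by
a residual connection.  With K_M = 0 the stage reduces exactly to standard
self-attention over the spatial tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .datamodel import FeatureMap
from .nn import Linear, Module

__all__ = [
    "FusionConfig",
    "Modulator",
    "CrossAttention",
    "MdfmCaf",
    "modulation_params",
    "modulate",
    "cross_attention",
    "fuse",
    "flatten_tokens",
    "unflatten_tokens",
]


@dataclass(frozen=True)
class FusionConfig:
    channels: int = 2048   # C
    embed_dim: int = 512   # d


def flatten_tokens(F: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, N, C) with N = H·W, row-major over the grid."""
    B, C, H, W = F.shape
    return F.reshape(B, C, H * W).transpose(0, 2, 1)


def unflatten_tokens(X: Tensor, H: int, W: int) -> Tensor:
    """(B, N, C) -> (B, C, H, W); inverse of :func:`flatten_tokens`."""
    B, N, C = X.shape
    if N != H * W:
        raise ValueError(f"token count {N} != {H}x{W}")
    return X.transpose(0, 2, 1).reshape(B, C, H, W)


class Modulator(Module):
    """γ = W_γ·e_M + b_γ, β = W_β·e_M + b_β (both C-dim)."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.gamma_fc = Linear(cfg.embed_dim, cfg.channels, rng)
        self.beta_fc = Linear(cfg.embed_dim, cfg.channels, rng)
        # start at identity modulation (γ ≈ 1, β ≈ 0) for stable early training
        self.gamma_fc.weight.data *= 0.01
        self.gamma_fc.bias.data += 1.0
        self.beta_fc.weight.data *= 0.01

    def forward(self, e_M: Tensor) -> tuple[Tensor, Tensor]:
        return self.gamma_fc(e_M), self.beta_fc(e_M)


def modulation_params(e_M: Tensor, modulator: Modulator) -> tuple[Tensor, Tensor]:
    return modulator(e_M)


def modulate(F: Tensor | FeatureMap, gamma, beta):
    """F''_c = γ_c · F'_c + β_c, broadcast over the spatial grid."""
    as_map = isinstance(F, FeatureMap)
    x = Tensor(F.values) if as_map else F
    g = gamma if isinstance(gamma, Tensor) else Tensor(np.asarray(gamma))
    b = beta if isinstance(beta, Tensor) else Tensor(np.asarray(beta))
    C = x.shape[-3]
    if g.shape[-1] != C or b.shape[-1] != C:
        raise ValueError(f"modulation length mismatch with C={C}")
    if x.ndim == 3:
        out = x * g.reshape(C, 1, 1) + b.reshape(C, 1, 1)
    else:
        out = x * g.reshape(g.shape[0], C, 1, 1) + b.reshape(b.shape[0], C, 1, 1)
    if as_map:
        return FeatureMap(out.data, stage="modulated")
    return out


class CrossAttention(Module):
    """Single-head scaled dot-product attention over spatial tokens with a
    metadata key added to every key row."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.q = Linear(cfg.channels, cfg.channels, rng)
        self.k = Linear(cfg.channels, cfg.channels, rng)
        self.v = Linear(cfg.channels, cfg.channels, rng)
        self.k_meta = Linear(cfg.embed_dim, cfg.channels, rng)
        self.channels = cfg.channels

    def forward(self, F: Tensor, e_M: Tensor) -> Tensor:
        """(B, C, H, W), (B, d) -> attention output (B, C, H, W)."""
        B, C, H, W = F.shape
        X = flatten_tokens(F)                       # (B, N, C)
        Q, K, V = self.q(X), self.k(X), self.v(X)
        K_M = self.k_meta(e_M).reshape(B, 1, C)     # broadcast to every key row
        scores = (Q @ (K + K_M).transpose(0, 2, 1)) * (1.0 / np.sqrt(C))
        if not np.all(np.isfinite(scores.data)):
            raise FloatingPointError(
                f"non-finite attention scores (max logit "
                f"{np.nanmax(np.abs(scores.data)):.3g})")
        A = scores.softmax(axis=-1) @ V             # (B, N, C)
        return unflatten_tokens(A, H, W)


def cross_attention(F, e_M, attn: CrossAttention):
    """Functional wrapper; accepts FeatureMap or batched Tensor."""
    as_map = isinstance(F, FeatureMap)
    x = Tensor(F.values[None]) if as_map else F
    e = e_M if isinstance(e_M, Tensor) else Tensor(np.atleast_2d(np.asarray(e_M)))
    out = attn(x, e)
    if as_map:
        return FeatureMap(out.data[0], stage="attention")
    return out


def fuse(F, A):
    """Residual fusion F_fused = F'' + A."""
    as_map = isinstance(F, FeatureMap)
    x = Tensor(F.values) if as_map else F
    a = Tensor(A.values) if isinstance(A, FeatureMap) else A
    if x.shape != a.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {a.shape}")
    out = x + a
    if as_map:
        return FeatureMap(out.data, stage="fused")
    return out


class MdfmCaf(Module):
    """modulate -> cross-attend -> residual-fuse."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.modulator = Modulator(cfg, rng)
        self.attn = CrossAttention(cfg, rng)

    def forward(self, F: Tensor, e_M: Tensor) -> Tensor:
        gamma, beta = self.modulator(e_M)
        F_mod = modulate(F, gamma, beta)
        A = self.attn(F_mod, e_M)
        return F_mod + A


def mdfm_caf_forward(F, e_M, module: MdfmCaf):
    """Full two-stage fusion on a single recalibrated FeatureMap."""
    if isinstance(F, FeatureMap) and F.stage not in ("recalibrated", "backbone"):
        raise ValueError(f"expected a recalibrated feature map, got stage {F.stage!r}")
    as_map = isinstance(F, FeatureMap)
    x = Tensor(F.values[None]) if as_map else F
    e = e_M if isinstance(e_M, Tensor) else Tensor(np.atleast_2d(np.asarray(e_M)))
    out = module(x, e)
    if as_map:
        return FeatureMap(out.data[0], stage="fused")
    return out
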