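"""Dual-modality integrated-gradients attribution.

Path-integral attribution from a baseline to the input, approximated with a
midpoint Riemann sum (midpoints have lower bias than left endpoints at
equal step count).  The image path holds metadata fixed and vice versa; the
completeness residual |ΣIG − (S_c(x) − S_c(x'))| is recorded on each
result, never hidden.  Image baseline defaults to the zero (normalised)
image; the metadata baseline defaults to the neutral all-"unknown"/mid-range
encoding, because the all-zero vector is not a valid point of the one-hot
encoding space.  Attribution targets the softmax score by default, with the
pre-softmax logit available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .nn import Module
from .schema import MetadataSchema

__all__ = [
    "AttributionResult",
    "BaselinePolicy",
    "attribute_sample",
    "integrated_gradients_image",
    "integrated_gradients_metadata",
    "normalize_heatmap",
    "unified_ranking",
    "save_attribution_artifacts",
]


@dataclass
class BaselinePolicy:
    """Image baseline I' and metadata baseline M'."""

    image_baseline: np.ndarray | None = None     # None -> zero image
    metadata_baseline: np.ndarray | None = None  # None -> neutral encoding

    def image(self, like: np.ndarray) -> np.ndarray:
        if self.image_baseline is None:
            return np.zeros_like(like)
        base = np.asarray(self.image_baseline, dtype=float)
        if base.shape != like.shape:
            raise ValueError(f"image baseline shape {base.shape} != input {like.shape}")
        return base

    def metadata(self, like: np.ndarray) -> np.ndarray:
        if self.metadata_baseline is None:
            return MetadataSchema.default().neutral_vector().values
        base = np.asarray(self.metadata_baseline, dtype=float)
        if base.shape != like.shape:
            raise ValueError(f"metadata baseline shape {base.shape} != input {like.shape}")
        return base


@dataclass
class AttributionResult:
    sample_id: str
    target_class: int
    pixel_attribution: np.ndarray          # (S, S): signed, channel-summed
    metadata_scores: np.ndarray            # (81,): signed
    pixel_heatmap: np.ndarray              # (S, S): normalised to [0, 1]
    completeness_residual_image: float
    completeness_residual_metadata: float
    steps: int
    signed_heatmap: bool = False

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def _score(model: Module, I: np.ndarray, M: np.ndarray, c: int,
           on: str = "softmax") -> float:
    from .autodiff import no_grad
    with no_grad():
        logits = model(Tensor(I[None]), Tensor(M[None]))
    if on == "softmax":
        return float(logits.softmax(axis=-1).data[0, c])
    return float(logits.data[0, c])


def _midpoints(steps: int) -> np.ndarray:
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return (np.arange(steps) + 0.5) / steps


def integrated_gradients_image(model: Module, I: np.ndarray, M: np.ndarray,
                               c: int, policy: BaselinePolicy | None = None,
                               steps: int = 50, on: str = "softmax"):
    """Per-pixel IG (3, S, S) and the completeness residual.

    IG_{i,j} = (I − I')_{i,j} × midpoint-Riemann mean of ∂S_c/∂I_{i,j}
    along the straight path, metadata held fixed at M.
    """
    policy = policy or BaselinePolicy()
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    base = policy.image(I)
    alphas = _midpoints(steps)
    path = base[None] + alphas[:, None, None, None] * (I - base)[None]

    model_was = model.training
    model.eval()
    try:
        X = Tensor(path, requires_grad=True)
        Mb = Tensor(np.broadcast_to(M, (steps,) + M.shape).copy())
        logits = model(X, Mb)
        score = logits.softmax(axis=-1)[:, c] if on == "softmax" else logits[:, c]
        score.sum().backward()
        grads = X.grad
        if grads is None:
            grads = np.zeros_like(path)
        if not np.all(np.isfinite(grads)):
            bad = int(np.where(~np.isfinite(grads.reshape(steps, -1)).all(axis=1))[0][0])
            raise FloatingPointError(f"NaN gradient at interpolation step {bad}")
        ig = (I - base) * grads.mean(axis=0)
        gap = _score(model, I, M, c, on) - _score(model, base, M, c, on)
    finally:
        model.train(model_was)
    residual = abs(float(ig.sum()) - gap)
    return ig, residual


def integrated_gradients_metadata(model: Module, I: np.ndarray, M: np.ndarray,
                                  c: int, policy: BaselinePolicy | None = None,
                                  steps: int = 50, on: str = "softmax"):
    """Per-metadata-dimension IG (81,) and completeness residual; image fixed."""
    policy = policy or BaselinePolicy()
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    base = policy.metadata(M)
    alphas = _midpoints(steps)
    path = base[None] + alphas[:, None] * (M - base)[None]

    model_was = model.training
    model.eval()
    try:
        Mx = Tensor(path, requires_grad=True)
        Ib = Tensor(np.broadcast_to(I, (steps,) + I.shape).copy())
        logits = model(Ib, Mx)
        score = logits.softmax(axis=-1)[:, c] if on == "softmax" else logits[:, c]
        score.sum().backward()
        grads = Mx.grad
        if grads is None:
            grads = np.zeros_like(path)
        if not np.all(np.isfinite(grads)):
            bad = int(np.where(~np.isfinite(grads).all(axis=1))[0][0])
            raise FloatingPointError(f"NaN gradient at interpolation step {bad}")
        ig = (M - base) * grads.mean(axis=0)
        gap = _score(model, I, M, c, on) - _score(model, I, base, c, on)
    finally:
        model.train(model_was)
    residual = abs(float(ig.sum()) - gap)
    return ig, residual


def normalize_heatmap(raw: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant map maps to all-0.5 by convention."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("heatmap contains non-finite entries")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def unified_ranking(pixel_map: np.ndarray, metadata_scores: np.ndarray):
    """Single descending ranking over all pixels + metadata dimensions.

    Items are ("meta", k) or ("pixel", flat_index) with flat row-major pixel
    indexing; sorted by |attribution| descending, ties broken by
    (modality, index) lexicographic order.  Returns [((modality, index),
    abs_attribution), ...].
    """
    pixel_map = np.asarray(pixel_map, dtype=float)
    metadata_scores = np.asarray(metadata_scores, dtype=float)
    items = [(("meta", int(k)), abs(float(v))) for k, v in enumerate(metadata_scores)]
    items += [(("pixel", int(i)), abs(float(v)))
              for i, v in enumerate(pixel_map.ravel(order="C"))]
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))


def attribute_sample(model: Module, I: np.ndarray, M: np.ndarray, c: int,
                     policy: BaselinePolicy | None = None, steps: int = 50,
                     on: str = "softmax", sample_id: str = "sample",
                     signed_heatmap: bool = False) -> AttributionResult:
    """Full dual-modality attribution for one (sample, class)."""
    ig_img, res_img = integrated_gradients_image(model, I, M, c, policy, steps, on)
    ig_meta, res_meta = integrated_gradients_metadata(model, I, M, c, policy, steps, on)
    pixel = ig_img.sum(axis=0)  # channel-summed signed per-pixel attribution
    heat = normalize_heatmap(pixel if signed_heatmap else np.abs(pixel))
    return AttributionResult(
        sample_id=sample_id, target_class=int(c), pixel_attribution=pixel,
        metadata_scores=ig_meta, pixel_heatmap=heat,
        completeness_residual_image=res_img, completeness_residual_metadata=res_meta,
        steps=steps, signed_heatmap=signed_heatmap)


def save_attribution_artifacts(result: AttributionResult, out_dir,
                               attribute_names: list[str] | None = None) -> dict[str, Path]:
    """Heatmap PNG + raw CSV, metadata bar plot PNG + CSV, composite figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = result.sample_id
    paths = {}

    heat_png = out_dir / f"{sid}_heatmap.png"
    plt.imsave(heat_png, result.pixel_heatmap, cmap="inferno", vmin=0, vmax=1)
    paths["heatmap_png"] = heat_png

    raw_csv = out_dir / f"{sid}_pixel_attribution.csv"
    np.savetxt(raw_csv, result.pixel_attribution, delimiter=",")
    paths["pixel_csv"] = raw_csv

    names = attribute_names or [f"dim_{k}" for k in range(len(result.metadata_scores))]
    meta_csv = out_dir / f"{sid}_metadata_scores.csv"
    pd.DataFrame({"feature": names, "score": result.metadata_scores}).to_csv(
        meta_csv, index=False)
    paths["metadata_csv"] = meta_csv

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].imshow(result.pixel_heatmap, cmap="inferno", vmin=0, vmax=1)
    axes[0].set_title(f"{sid}: pixel attribution (class {result.target_class})")
    axes[0].axis("off")
    top = np.argsort(-np.abs(result.metadata_scores))[:15]
    axes[1].barh([names[k] for k in top][::-1],
                 result.metadata_scores[top][::-1])
    axes[1].set_title("top metadata attributions")
    fig.tight_layout()
    composite = out_dir / f"{sid}_composite.png"
    fig.savefig(composite, dpi=100)
    plt.close(fig)
    paths["composite_png"] = composite
    return paths
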