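"""Uncertainty-weighted focal loss and the training recipe.

SGD with momentum 0.9 and weight decay 0.001, initial learning rate 0.001
under cosine annealing, batch size 8, focal loss with focusing exponent
γ = 2 and static class weights [1, 1, 2, 1, 2, 1] (MEL and SCC up-weighted).
When uncertainty weighting is on, every batch additionally runs T
Monte-Carlo-dropout passes; the per-sample true-class softmax variance maps
through w = 1/(1+exp(−λσ²)) and multiplies the static weight.  Channel-gate
snapshots are persisted on a fixed epoch cadence and attribution artifacts
for the first validation sample once validation BACC/ACC cross the save
thresholds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .amcr import uncertainty_weight
from .autodiff import Tensor, no_grad
from .datamodel import Sample
from .metrics import ConfusionSummary, accuracy, bacc
from .network import predict_proba
from .nn import Module, Parameter, mc_dropout_mode, seed_dropout

__all__ = [
    "FocalLossConfig",
    "TrainConfig",
    "TrainingDiverged",
    "SGD",
    "cosine_lr",
    "focal_loss",
    "focal_loss_batch",
    "samples_to_arrays",
    "train",
]

_LOG_EPS = 1e-8


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class FocalLossConfig:
    gamma: float = 2.0
    static_alpha: tuple[float, ...] = (1.0, 1.0, 2.0, 1.0, 2.0, 1.0)
    lam: float = 0.1
    use_uncertainty: bool = True

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("focusing exponent must be >= 0")
        if any(a <= 0 for a in self.static_alpha):
            raise ValueError("static alphas must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 8
    lr0: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.001
    t_max: int | None = None          # cosine period; defaults to epochs
    clip_norm: float = 5.0            # global gradient-norm clip (0 disables)
    mc_passes: int = 10               # T for per-batch uncertainty weights
    seed: int = 0
    snapshot_every: int = 10          # channel-gate snapshot cadence (epochs)
    save_bacc_threshold: float = 0.82  # attribution artifacts saved past these
    save_acc_threshold: float = 0.86
    focal: FocalLossConfig = field(default_factory=FocalLossConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size and lr0 must be positive")
        if (self.t_max or self.epochs) < 1:
            raise ValueError("t_max must be >= 1")


def focal_loss(S, y: int, cfg: FocalLossConfig, w: float = 1.0) -> float:
    """Per-sample focal loss −α_y · w · (1 − S_y)^γ · log(S_y).

    `w` is the uncertainty weight (1 when uncertainty weighting is off);
    S_y is clamped at 1e-8 before the log.
    """
    S = np.asarray(S, dtype=float)
    s_y = max(float(S[y]), _LOG_EPS)
    alpha_y = cfg.static_alpha[y]
    return -alpha_y * w * (1.0 - s_y) ** cfg.gamma * np.log(s_y)


def focal_loss_batch(logits: Tensor, y: np.ndarray, cfg: FocalLossConfig,
                     weights: np.ndarray | None = None) -> Tensor:
    """Mean focal loss over a batch, differentiable through the logits."""
    n = logits.shape[0]
    probs = logits.softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), y] = 1.0
    s_y = (probs * onehot).sum(axis=-1)                      # (B,)
    alpha_y = np.asarray(cfg.static_alpha)[y]
    w = np.ones(n) if weights is None else np.asarray(weights)
    s_clamped = s_y + (s_y.data < _LOG_EPS) * _LOG_EPS       # clamp only when ~0
    per_sample = (1.0 - s_y) ** cfg.gamma * s_clamped.log() * (-alpha_y * w)
    return per_sample.mean()


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """lr(t) = lr0 · (1 + cos(π t / T_max)) / 2, clamped to 0 past T_max."""
    t_max = cfg.t_max or cfg.epochs
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= t_max:
        return 0.0
    return cfg.lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / t_max))


class SGD:
    """Momentum SGD with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params: list[Parameter], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float, clip_norm: float = 0.0):
        if clip_norm > 0:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > clip_norm:
                scale = clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - lr * v


def samples_to_arrays(samples: list[Sample]):
    images = np.stack([s.image.pixels for s in samples])
    metadata = np.stack([s.metadata.values for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return images, metadata, labels


def _mc_batch_variance(model: Module, I: np.ndarray, M: np.ndarray,
                       T: int, seed: int) -> np.ndarray:
    """(B, n_classes) softmax variance over T MC-dropout passes on a batch."""
    draws = []
    with mc_dropout_mode(model):
        seed_dropout(model, seed)
        for _ in range(T):
            with no_grad():
                logits = model(Tensor(I), Tensor(M))
            draws.append(logits.softmax(axis=-1).data)
    return np.stack(draws).var(axis=0)


def evaluate_bacc_acc(model: Module, samples: list[Sample]) -> tuple[float, float, np.ndarray]:
    I, M, y = samples_to_arrays(samples)
    scores = predict_proba(model, I, M)
    cm = ConfusionSummary.from_labels(y, scores.argmax(axis=1), n_classes=scores.shape[1])
    try:
        b = bacc(cm)
    except ValueError:  # a class missing from this (tiny) evaluation set
        recalls = [cm.tp(i) / (cm.tp(i) + cm.fn(i))
                   for i in range(cm.n_classes) if cm.tp(i) + cm.fn(i) > 0]
        b = 100.0 * float(np.mean(recalls))
    return b, accuracy(cm), scores


def train(model: Module, train_samples: list[Sample], val_samples: list[Sample],
          cfg: TrainConfig, artifact_dir: str | Path | None = None,
          attribution_hook=None) -> dict:
    """Train in place; returns {"history": [...], "best_state": ..., "best_epoch": ...}.

    `attribution_hook(model, epoch, out_dir)` is invoked once validation
    BACC/ACC cross the configured save thresholds (attribution artifacts for
    high-performing checkpoints only).
    """
    rng = np.random.default_rng(cfg.seed)
    seed_dropout(model, cfg.seed + 1)
    I, M, y = samples_to_arrays(train_samples)
    n = len(train_samples)
    opt = SGD(model.parameters(), momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    # warm batch-norm running statistics so MC-dropout passes (which freeze
    # them) are well-defined from the first batch onward
    model.train()
    with no_grad():
        warm = min(n, max(cfg.batch_size, 2))
        model(Tensor(I[:warm]), Tensor(M[:warm]))
    history: list[dict] = []
    best = {"bacc": -1.0, "acc": -1.0, "state": None, "epoch": -1}
    artifact_dir = Path(artifact_dir) if artifact_dir is not None else None
    if artifact_dir is not None:
        artifact_dir.mkdir(parents=True, exist_ok=True)
    alpha_rows = []

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        order = rng.permutation(n)
        model.train()
        losses = []
        for b_idx, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            Ib, Mb, yb = I[idx], M[idx], y[idx]
            weights = None
            if cfg.focal.use_uncertainty:
                var = _mc_batch_variance(model, Ib, Mb, cfg.mc_passes,
                                         seed=cfg.seed + 7919 * epoch + b_idx)
                weights = uncertainty_weight(var[np.arange(len(yb)), yb], cfg.focal.lam)
                model.train()
            model.zero_grad()
            logits = model(Tensor(Ib), Tensor(Mb))
            loss = focal_loss_batch(logits, yb, cfg.focal, weights)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {b_idx}")
            loss.backward()
            opt.step(lr, clip_norm=cfg.clip_norm)
            losses.append(float(loss.data))

        val_bacc, val_acc, _ = evaluate_bacc_acc(model, val_samples)
        history.append({"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)),
                        "val_bacc": val_bacc, "val_acc": val_acc})
        if (val_bacc, val_acc) > (best["bacc"], best["acc"]):
            best = {"bacc": val_bacc, "acc": val_acc,
                    "state": model.state_dict(), "epoch": epoch}
        if hasattr(model, "attention") and (epoch + 1) % cfg.snapshot_every == 0:
            # mean channel gate over (up to 64) validation samples
            Iv, Mv, _ = samples_to_arrays(val_samples[:64])
            model.eval()
            with no_grad():
                model(Tensor(Iv), Tensor(Mv))
            mean_alpha = np.atleast_2d(model.last_alpha).mean(axis=0)
            alpha_rows += [(epoch, c, float(a)) for c, a in enumerate(mean_alpha)]
        if attribution_hook is not None and artifact_dir is not None and \
                (val_bacc > 100 * cfg.save_bacc_threshold or
                 val_acc > 100 * cfg.save_acc_threshold):
            attribution_hook(model, epoch, artifact_dir)

    if artifact_dir is not None and alpha_rows:
        with open(artifact_dir / "alpha_snapshots.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "channel_index", "mean_alpha"])
            writer.writerows(alpha_rows)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return {"history": history, "best_state": best["state"], "best_epoch": best["epoch"],
            "best_bacc": best["bacc"], "best_acc": best["acc"]}


def write_history_csv(history: list[dict], path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss",
                                                "val_bacc", "val_acc"])
        writer.writeheader()
        writer.writerows(history)
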