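"""Quantitative attribution faithfulness: insertion/deletion AUC and a
ratio-form faithfulness drop.

The protocol is the standard incremental reveal/removal one: starting from
the baseline (insertion) or the full input (deletion), features are flipped
in ranking order at a grid of fractions while the model's class score is
recorded; the trapezoidal area under the score-vs-fraction curve is the
metric (higher insertion / lower deletion = more faithful ranking).
Features are pixels (all three colour channels move together) and, in
unified mode, individual metadata dimensions interleaved into the same
ranking.  The faithfulness drop is the ratio of the score drop caused by
deleting the top-q fraction of features to the mean drop over R random
q-fractions; values above 1 mean the attributed regions are more critical
than chance.  The ratio form is this package's reconstruction of the
protocol and is labelled as such in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Module

__all__ = [
    "PerturbationCurve",
    "default_grid",
    "insertion_auc",
    "deletion_auc",
    "faithfulness_drop",
    "make_score_fn",
    "coarse_pixel_ranking",
    "pixel_ranking_from_map",
]


@dataclass
class PerturbationCurve:
    fractions: np.ndarray
    scores: np.ndarray
    direction: str  # "insertion" | "deletion"

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.diff(self.fractions) > 0):
            raise ValueError("fractions must be strictly increasing")
        if self.fractions[0] != 0.0 or self.fractions[-1] != 1.0:
            raise ValueError("fractions must run from 0 to 1")

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.scores, self.fractions))


def default_grid() -> np.ndarray:
    """20 evenly spaced interior fractions plus the two endpoints."""
    return np.linspace(0.0, 1.0, 22)


def make_score_fn(model: Module, c: int, on: str = "softmax"):
    """Adapter: (I, M) -> S_c under deterministic eval mode."""

    def score(I: np.ndarray, M: np.ndarray) -> float:
        was = model.training
        model.eval()
        try:
            with no_grad():
                logits = model(Tensor(np.asarray(I)[None]), Tensor(np.asarray(M)[None]))
            if on == "softmax":
                return float(logits.softmax(axis=-1).data[0, c])
            return float(logits.data[0, c])
        finally:
            model.train(was)

    return score


def _check_ranking(ranking, n_pixels: int, n_meta: int):
    ids = [fid for fid, _ in ranking] if ranking and isinstance(ranking[0], tuple) \
        and len(ranking[0]) == 2 and isinstance(ranking[0][0], tuple) else list(ranking)
    expected = {("pixel", i) for i in range(n_pixels)}
    expected |= {("meta", k) for k in range(n_meta)}
    if set(ids) != expected or len(ids) != len(expected):
        raise ValueError("ranking is not a permutation of the rankable features")
    return ids


def _apply_feature(I: np.ndarray, M: np.ndarray, src_I: np.ndarray,
                   src_M: np.ndarray, fid):
    kind, idx = fid
    if kind == "pixel":
        S = I.shape[-1]
        i, j = divmod(idx, S)
        I[:, i, j] = src_I[:, i, j]
    else:
        M[idx] = src_M[idx]


def _perturbation_curve(score_fn, I, M, I_base, M_base, ranking, grid,
                        direction: str) -> PerturbationCurve:
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    I_base = np.asarray(I_base, dtype=float)
    M_base = np.asarray(M_base, dtype=float)
    n_pixels = I.shape[-1] * I.shape[-2]
    meta_ids = [fid for fid in ([f for f, _ in ranking] if ranking and
                isinstance(ranking[0][0], tuple) else ranking) if fid[0] == "meta"]
    n_meta = len(meta_ids)
    ids = _check_ranking(ranking, n_pixels, n_meta)

    if direction == "insertion":
        cur_I, cur_M = I_base.copy(), M_base.copy()
        src_I, src_M = I, M
    else:
        cur_I, cur_M = I.copy(), M.copy()
        src_I, src_M = I_base, M_base

    grid = np.asarray(grid, dtype=float)
    K = len(ids)
    scores, done = [], 0
    for f in grid:
        k = int(round(f * K))
        for fid in ids[done:k]:
            _apply_feature(cur_I, cur_M, src_I, src_M, fid)
        done = max(done, k)
        scores.append(score_fn(cur_I, cur_M))
    return PerturbationCurve(grid, np.array(scores), direction)


def insertion_auc(score_fn, I, M, I_base, M_base, ranking,
                  grid=None) -> tuple[float, PerturbationCurve]:
    """Reveal features in ranking order starting from the baseline."""
    curve = _perturbation_curve(score_fn, I, M, I_base, M_base, ranking,
                                default_grid() if grid is None else grid, "insertion")
    return curve.auc, curve


def deletion_auc(score_fn, I, M, I_base, M_base, ranking,
                 grid=None) -> tuple[float, PerturbationCurve]:
    """Replace features with the baseline in ranking order from the full input."""
    curve = _perturbation_curve(score_fn, I, M, I_base, M_base, ranking,
                                default_grid() if grid is None else grid, "deletion")
    return curve.auc, curve


def faithfulness_drop(score_fn, I, M, I_base, M_base, ranking, q: float = 0.2,
                      R: int = 20, seed: int = 0) -> float:
    """(top-q attributed deletion drop) / (mean random q-fraction drop).

    NaN flags the undefined case of a ~zero mean random drop (e.g. a model
    constant in its inputs).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if R < 1:
        raise ValueError("R must be >= 1")
    I = np.asarray(I, dtype=float)
    M = np.asarray(M, dtype=float)
    I_base = np.asarray(I_base, dtype=float)
    M_base = np.asarray(M_base, dtype=float)
    ids = _check_ranking(ranking, I.shape[-1] * I.shape[-2],
                         sum(1 for fid in ([f for f, _ in ranking] if ranking and
                             isinstance(ranking[0][0], tuple) else ranking)
                             if fid[0] == "meta"))
    K = len(ids)
    k = max(1, int(np.ceil(q * K)))
    full = score_fn(I, M)

    def drop_for(subset) -> float:
        cur_I, cur_M = I.copy(), M.copy()
        for fid in subset:
            _apply_feature(cur_I, cur_M, I_base, M_base, fid)
        return full - score_fn(cur_I, cur_M)

    top_drop = drop_for(ids[:k])
    rng = np.random.default_rng(seed)
    random_drops = [drop_for([ids[i] for i in rng.choice(K, size=k, replace=False)])
                    for _ in range(R)]
    mean_random = float(np.mean(random_drops))
    if abs(mean_random) < 1e-12:
        return float("nan")
    return top_drop / mean_random


# ---------------------------------------------------------------------------
# rankings


def pixel_ranking_from_map(pixel_map: np.ndarray):
    """Pixel-only ranking (no metadata features) from an attribution map."""
    pixel_map = np.asarray(pixel_map, dtype=float)
    flat = np.abs(pixel_map.ravel(order="C"))
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    return [("pixel", i) for i in order]


def coarse_pixel_ranking(pixel_map: np.ndarray, cells: int = 7):
    """Grad-CAM-style coarse ranking: every pixel scores as the mean
    |attribution| of its cells×cells block, so fine detail is lost."""
    pixel_map = np.abs(np.asarray(pixel_map, dtype=float))
    S = pixel_map.shape[0]
    block = int(np.ceil(S / cells))
    coarse_score = np.empty_like(pixel_map)
    for bi in range(0, S, block):
        for bj in range(0, S, block):
            patch = pixel_map[bi:bi + block, bj:bj + block]
            coarse_score[bi:bi + block, bj:bj + block] = patch.mean()
    flat = coarse_score.ravel(order="C")
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    return [("pixel", i) for i in order]
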