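"""Shared fixtures: tiny synthetic datasets, a trained tiny classifier, and
toy differentiable models with known closed-form attributions."""

import numpy as np
import pytest

from dermafuse.autodiff import Tensor
from dermafuse.estimator import LesionClassifier
from dermafuse.nn import Dropout, Module
from dermafuse.synthetic import GeneratorConfig, SplitSpec, generate_dataset, stratified_split
from dermafuse.train import samples_to_arrays


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 samples, 32-pixel images, default class imbalance."""
    return generate_dataset(GeneratorConfig(total_n=120, image_size=32, seed=1))


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return stratified_split(list(tiny_dataset), SplitSpec(seed=0))


@pytest.fixture(scope="session")
def trained_clf(tiny_split):
    """A briefly trained tiny multimodal classifier (shared; do not mutate)."""
    tr, va, _ = tiny_split
    I, M, y = samples_to_arrays(tr)
    Iv, Mv, yv = samples_to_arrays(va)
    clf = LesionClassifier(epochs=3, mc_passes=2, seed=0)
    clf.fit((I, M), y, X_val=(Iv, Mv), y_val=yv)
    return clf


def finite_difference(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


class LinearLogitModel(Module):
    """logits = [<w_img, I> + <w_meta, M>, 0]: closed-form IG on the logit."""

    def __init__(self, w_img: np.ndarray, w_meta: np.ndarray):
        super().__init__()
        self.w_img = np.asarray(w_img, dtype=float)
        self.w_meta = np.asarray(w_meta, dtype=float)

    def forward(self, I: Tensor, M: Tensor) -> Tensor:
        B = I.shape[0]
        W_i = np.vstack([self.w_img.ravel(), np.zeros(self.w_img.size)])
        W_m = np.vstack([self.w_meta, np.zeros_like(self.w_meta)])
        return I.reshape(B, -1) @ Tensor(W_i.T) + M @ Tensor(W_m.T)


class SigmoidPixelModel(Module):
    """Nonlinear toy: logits = [sigmoid(<w, I>)·s, 0]; IG needs quadrature."""

    def __init__(self, w_img: np.ndarray, scale: float = 3.0):
        super().__init__()
        self.w_img = np.asarray(w_img, dtype=float)
        self.scale = scale

    def forward(self, I: Tensor, M: Tensor) -> Tensor:
        B = I.shape[0]
        W = np.vstack([self.w_img.ravel(), np.zeros(self.w_img.size)])
        z = I.reshape(B, -1) @ Tensor(W.T)
        return z.sigmoid() * self.scale


class CycleModel(Module):
    """Returns preset logits in rotation, one per forward call."""

    def __init__(self, logits_sequence):
        super().__init__()
        self.seq = [np.asarray(l, dtype=float) for l in logits_sequence]
        self.calls = 0

    def forward(self, I, M):
        out = self.seq[self.calls % len(self.seq)]
        self.calls += 1
        return Tensor(out[None])


class NoisyScalarModel(Module):
    """Single dropout site on a constant: stochastic softmax for MC tests."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.drop = Dropout(p)

    def forward(self, I, M):
        h = self.drop(Tensor(np.array([[2.0, 0.0]])))
        return h
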