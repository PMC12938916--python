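"""Neural-network layers built on the autodiff engine.

Provides the handful of layer types the lesion networks need: linear maps,
2-D convolutions, batch normalisation, dropout (with a Monte-Carlo override
so dropout can stay stochastic while batch-norm statistics are frozen), and
a module container with parameter traversal and flat state dicts for
checkpointing.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "Dropout",
    "ReLU",
    "Sequential",
    "mc_dropout_mode",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters track gradients even under no_grad construction


class Module:
    """Base class: submodule/parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- mode ----------------------------------------------------------------
    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------------
    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(prefix=f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = {}

        def collect(mod: Module, prefix: str):
            for name, value in vars(mod).items():
                full = f"{prefix}{name}"
                if isinstance(value, Module):
                    collect(value, full + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            collect(item, f"{full}.{i}.")
                elif name.startswith("running_"):  # buffer slot, may be None
                    bufs[full] = (mod, name)

        collect(self, "")
        for name, array in state.items():
            if name in params:
                if params[name].data.shape != array.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {array.shape}")
                params[name].data = np.asarray(array, dtype=np.float64).copy()
            elif name in bufs:
                mod, attr = bufs[name]
                setattr(mod, attr, np.asarray(array, dtype=np.float64).copy())
            else:
                raise KeyError(f"unexpected state entry {name!r}")


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm1d(Module):
    """Batch normalisation over the batch axis of a (B, d) tensor.

    Training mode normalises with batch statistics and updates running
    estimates; evaluation mode requires initialised running statistics and
    raises otherwise (an untrained network has no population estimate).
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean: np.ndarray | None = None
        self.running_var: np.ndarray | None = None

    def set_running_stats(self, mean, var):
        self.running_mean = np.asarray(mean, dtype=np.float64).copy()
        self.running_var = np.asarray(var, dtype=np.float64).copy()

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred ** 2.0).mean(axis=0, keepdims=True)
            xhat = centred * (var + self.eps) ** -0.5
            batch_mean = mu.data.ravel()
            batch_var = var.data.ravel()
            if self.running_mean is None:
                self.running_mean = batch_mean.copy()
                self.running_var = batch_var.copy()
            else:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * batch_mean
                self.running_var = (1 - m) * self.running_var + m * batch_var
        else:
            if self.running_mean is None:
                raise RuntimeError(
                    "BatchNorm1d used in eval mode before running statistics were "
                    "initialised; run a training pass or call set_running_stats()")
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout.  `force_active` keeps it stochastic in eval mode,
    which is how Monte-Carlo dropout passes are run (batch norm frozen,
    dropout live)."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.force_active = False
        self.rng = np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        active = (self.training or self.force_active) and self.p > 0.0
        if not active:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


@contextlib.contextmanager
def mc_dropout_mode(model: Module):
    """Eval mode with dropout kept stochastic (Monte-Carlo dropout)."""
    was_training = model.training
    model.eval()
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    for d in drops:
        d.force_active = True
    try:
        yield model
    finally:
        for d in drops:
            d.force_active = False
        model.train(was_training)


def seed_dropout(model: Module, seed: int):
    """Give every dropout site an independent stream derived from `seed`."""
    ss = np.random.SeedSequence(seed)
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    for d, child in zip(drops, ss.spawn(max(len(drops), 1))):
        d.rng = np.random.default_rng(child)
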