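"""Layer abstractions on top of the autodiff core.

Mirrors the familiar Module/Parameter idiom: submodules and parameters
register themselves through attribute assignment, ``state_dict`` round-
trips weights and normalization buffers, and ``train()``/``eval()``
toggle dropout and batch-norm behaviour recursively.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Parameter, Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- mode / grads --------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32)
        for name, b in bufs.items():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
            self._seq.append(m)

    def __iter__(self):
        return iter(self._seq)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleDict(Module):
    def __init__(self, mapping: dict | None = None):
        super().__init__()
        self._keys = []
        for k, m in (mapping or {}).items():
            self[k] = m

    def __setitem__(self, key, module: Module):
        setattr(self, str(key), module)
        self._keys.append(str(key))

    def __getitem__(self, key) -> Module:
        return self._modules[str(key)]

    def __contains__(self, key):
        return str(key) in self._modules

    def items(self):
        return [(k, self._modules[k]) for k in self._keys]


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0, bias=False):
        super().__init__()
        self.stride, self.padding = stride, padding
        k = kernel_size
        self.weight = Parameter(np.zeros((out_channels, in_channels, k, k), np.float32))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x):
        return core.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.weight = Parameter(np.zeros((out_features, in_features), np.float32))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        return core.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x):
        return core.batchnorm2d(
            x,
            self.weight,
            self.bias,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class LayerNorm(Module):
    def __init__(self, num_features, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))

    def forward(self, x):
        return core.layernorm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x):
        return core.relu(x)


class GELU(Module):
    def forward(self, x):
        return core.gelu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return core.maxpool2d(x, self.kernel_size, self.stride, self.padding)


class Dropout(Module):
    """Inverted dropout drawing from a generator settable per run."""

    def __init__(self, p=0.1):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator):
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        return core.dropout(x, self.p, self.rng)


def reseed_dropout(model: Module, seed: int):
    """Give every dropout layer an independent child stream of ``seed``."""
    ss = np.random.SeedSequence(seed)
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    for m, child in zip(drops, ss.spawn(len(drops))):
        m.reseed(np.random.default_rng(child))


# ---------------------------------------------------------------------
# initialization


def kaiming_normal_(p: Parameter, rng: np.random.Generator):
    """He initialization, fan-out mode, for convolutions feeding ReLU."""
    fan_out = p.data.shape[0] * int(np.prod(p.data.shape[2:])) if p.data.ndim == 4 else p.data.shape[0]
    std = np.sqrt(2.0 / fan_out)
    p.data = (rng.standard_normal(p.data.shape) * std).astype(np.float32)


def trunc_normal_(p: Parameter, rng: np.random.Generator, std: float = 0.02):
    """Normal(0, std) truncated at two standard deviations (resampling)."""
    vals = rng.standard_normal(p.data.shape)
    bad = np.abs(vals) > 2.0
    while bad.any():
        vals[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(vals) > 2.0
    p.data = (vals * std).astype(np.float32)
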