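"""Layer abstractions over the autograd core: parameters, modules, and the
conv / norm / linear building blocks used by the fusion network."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
           "Linear", "ReLU", "Sequential", "init_normal"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Torch-like module: child tracking, parameter iteration, train/eval."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float64).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"]).copy()
                m.running_var = np.asarray(state[f"{name}.running_var"]).copy()

    def _named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{name}.")


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size,
                 stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        kh, kw = _pair(kernel_size)
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride, self.padding, self.groups = _pair(stride), _pair(padding), groups
        fan_in = in_channels // groups * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound,
                                             (out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, pad=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, bias=True):
        super().__init__()
        kh, kw = _pair(kernel_size)
        self.stride = _pair(stride)
        bound = 1.0 / np.sqrt(in_channels * kh * kw)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound,
                                             (in_channels, out_channels, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta,
                               self.running_mean, self.running_var,
                               training=self.training,
                               momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def init_normal(model: Module, rng: np.random.Generator, std: float = 0.1) -> None:
    """Initialize all conv / linear weights ~ N(0, std^2) (variance 0.01 at
    the default), biases 0; batch-norm scale/shift stay at 1/0."""
    for m in model.modules():
        if isinstance(m, (Conv2d, ConvTranspose2d, Linear)):
            m.weight.data = rng.normal(0.0, std, size=m.weight.data.shape)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, BatchNorm2d):
            m.gamma.data = np.ones_like(m.gamma.data)
            m.beta.data = np.zeros_like(m.beta.data)
            m.running_mean[:] = 0.0
            m.running_var[:] = 1.0
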