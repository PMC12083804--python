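"""A small torch-like module system on top of numpy + autograd.

Parameters are plain numpy arrays wrapped in :class:`Parameter`.  During a
gradient computation the trainer temporarily *overrides* each parameter's
value with an autograd box (see :func:`rscdnet.nn.optim.loss_and_gradients`);
forward code always reads ``param.value`` so the same implementation serves
both inference and training.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np
from autograd.tracer import getval

from . import functional as F

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Identity",
    "ReLU",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "GroupNorm",
    "MaxPool2d",
    "GlobalAvgPool2d",
]


class Parameter:
    """Trainable array with an optional traced-value override."""

    __slots__ = ("data", "_override")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self._override = None

    @property
    def value(self):
        return self.data if self._override is None else self._override

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: tracks child modules, parameters and train/eval mode."""

    def __init__(self):
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self._params: "OrderedDict[str, Parameter]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, val):
        if isinstance(val, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = val
        elif isinstance(val, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = val
        object.__setattr__(self, name, val)

    def register(self, name: str, module: "Module") -> "Module":
        setattr(self, name, module)
        return module

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- mode ------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: np.asarray(buf).copy() for name, buf in self.named_buffers()})
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"{state[name].shape} vs {p.data.shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        buffers = dict(self.named_buffers())
        for name, buf in buffers.items():
            if name in state:
                buf[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


def _kaiming_conv(rng: np.random.Generator, shape) -> np.ndarray:
    # fan-out normal init, as in He et al. conv practice
    c_out, _, kh, kw = shape
    fan_out = c_out * kh * kw
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("in/out channels must be divisible by groups")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Parameter(_kaiming_conv(rng, shape))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        b = self.bias.value if self.bias is not None else None
        return F.conv2d(x, self.weight.value, b, self.stride, self.padding,
                        self.groups)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return F.linear(x, self.weight.value, self.bias.value)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def named_buffers(self, prefix: str = ""):
        yield prefix + "running_mean", self.running_mean
        yield prefix + "running_var", self.running_var
        yield from super().named_buffers(prefix)

    def forward(self, x):
        if self.training:
            import autograd.numpy as anp

            mean = anp.mean(x, axis=(0, 2, 3))
            var = anp.mean((x - anp.reshape(mean, (1, -1, 1, 1))) ** 2, axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * getval(mean)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * getval(var) * unbias
            return F.batch_norm2d(x, self.weight.value, self.bias.value, mean, var, self.eps)
        return F.batch_norm2d(x, self.weight.value, self.bias.value,
                              self.running_mean, self.running_var, self.eps)


class GroupNorm(Module):
    def __init__(self, num_groups, num_channels, eps=1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("num_channels must be divisible by num_groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def forward(self, x):
        return F.group_norm2d(x, self.weight.value, self.bias.value,
                              self.num_groups, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    def forward(self, x):
        return F.global_avg_pool2d(x)
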