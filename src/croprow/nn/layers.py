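"""Layer / module abstractions on top of the autograd tensor.

Modules discover their parameters and submodules by scanning instance
attributes, so a network is declared exactly as a plain object graph.
Weight initialisation draws from a module-level RNG; call :func:`seed`
before building a model for reproducible initial weights.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

_RNG = np.random.default_rng(0)


def seed(value: int) -> None:
    """Reset the global weight-initialisation RNG."""
    global _RNG
    _RNG = np.random.default_rng(value)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------
    def named_members(self, prefix: str = ""):
        """Yield (name, Parameter) and recurse into child modules."""
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_members(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_members(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_members()]

    def modules(self):
        yield self
        for val in vars(self).items():
            pass
        for key, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- state --------------------------------------------------------
    def named_buffers(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, np.ndarray):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_members()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_members())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = arr
            else:
                p = params[key]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {arr.shape}")
                p.data = arr.astype(np.float32).copy()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _RNG.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 1,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = False):
        super().__init__()
        k = kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_kaiming((out_channels, in_channels, k, k),
                                         in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class DepthwiseConv2d(Module):
    """One k x k filter per channel (a grouped conv with groups == channels)."""

    def __init__(self, channels: int, kernel_size: int = 3, stride: int = 1,
                 dilation: int = 1):
        super().__init__()
        k = kernel_size
        self.stride, self.dilation = stride, dilation
        self.padding = dilation * (k - 1) // 2
        self.weight = Parameter(_kaiming((channels, k, k), k * k))

    def forward(self, x):
        return T.depthwise_conv2d(x, self.weight, stride=self.stride,
                                  padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return T.relu6(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> ReLU6, the MobileNetV2 building convention."""

    def __init__(self, cin: int, cout: int, kernel_size: int = 1, stride: int = 1,
                 dilation: int = 1, act: bool = True):
        super().__init__()
        pad = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(cin, cout, kernel_size, stride=stride, padding=pad,
                           dilation=dilation)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return T.relu6(x) if self.act else x


def count_parameters(module: Module) -> int:
    """Total number of trainable parameter elements."""
    return int(sum(p.data.size for p in module.parameters()))
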