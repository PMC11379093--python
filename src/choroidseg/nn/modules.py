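"""Layer containers built on the autodiff tensor: Conv2d, Linear,
LayerNorm2d, BatchNorm2d, plus parameter traversal and checkpoint state."""

from __future__ import annotations

import math

import numpy as np

from .functional import conv2d
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "LayerNorm2d",
    "BatchNorm2d",
    "zero_learnable_weights",
]


class Module:
    """Base class: attribute-order traversal of parameters, sub-modules and
    (non-learnable) buffers; train/eval mode; flat state dict."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # construction-time attribute scan; dict order == definition order
    def _children(self):
        for name, val in self.__dict__.items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in self.__dict__.items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, p in self.named_parameters(prefix):
            out[name] = p.data.copy()
        out.update(self._buffer_dict(prefix))
        return out

    def _buffer_dict(self, prefix: str = "") -> dict:
        out = {prefix + "__buf__" + k: v.copy() for k, v in self._buffers.items()}
        for name, child in self._children():
            out.update(child._buffer_dict(f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        own = self._buffer_refs()
        for key, val in state.items():
            if "__buf__" in key:
                own[key][...] = val
            else:
                params[key].data[...] = val

    def _buffer_refs(self, prefix: str = "") -> dict:
        out = {prefix + "__buf__" + k: v for k, v in self._buffers.items()}
        for name, child in self._children():
            out.update(child._buffer_refs(f"{prefix}{name}."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        fan_in = (in_channels // groups) * kh * kw
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.groups
        )


class Linear(Module):
    """Affine map on the trailing axis of an arbitrarily batched tensor."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = Tensor._coerce(x) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm2d(Module):
    """Layer normalization over the channel axis of [N,C,H,W] maps."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=1, keepdims=True)
        y = xc * ((v + self.eps) ** -0.5)
        c = self.gamma.data.size
        return y * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class BatchNorm2d(Module):
    """Batch normalization; eval mode uses running statistics (deterministic)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def forward(self, x: Tensor) -> Tensor:
        c = self.gamma.data.size
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            mom = self.momentum
            self._buffers["running_mean"] *= 1.0 - mom
            self._buffers["running_mean"] += mom * m.data.reshape(c)
            self._buffers["running_var"] *= 1.0 - mom
            self._buffers["running_var"] += mom * v.data.reshape(c)
            y = xc * ((v + self.eps) ** -0.5)
        else:
            rm = self._buffers["running_mean"].reshape(1, c, 1, 1)
            rv = self._buffers["running_var"].reshape(1, c, 1, 1)
            y = (x - rm) * ((rv + self.eps) ** -0.5)
        return y * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


def zero_learnable_weights(module: Module) -> Module:
    """Zero every convolution/linear weight and bias in place, leaving
    normalization scales identity-initialized.  Used to exercise the blocks'
    closed-form degenerate behaviour (e.g. sigmoid(0) = 1/2 gates)."""
    for m in module.modules():
        if isinstance(m, (Conv2d, Linear)):
            m.weight.data[...] = 0.0
            if m.bias is not None:
                m.bias.data[...] = 0.0
        elif hasattr(m, "weight") and isinstance(getattr(m, "weight"), Parameter):
            m.weight.data[...] = 0.0
            b = getattr(m, "bias", None)
            if isinstance(b, Parameter):
                b.data[...] = 0.0
    return module
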