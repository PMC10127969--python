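"""Torch-style modules on top of :mod:`mbsnet.autograd`.

Only what the network needs: stride-1 (optionally dilated / depthwise)
convolution, linear, batch / channel-layer normalization, the pooling and
upsampling variants of the encoder-decoder, and simple containers.  Spatial
modules operate on channel-last (N, H, W, C) tensors; the higher-level
blocks convert from the channel-first public interface.  Weights are
initialized Kaiming-uniform from a shared seeded generator.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- modes / grads -------------------------------------------------------
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

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for name, p in self.named_parameters():
            state["param." + name] = p.data.copy()
        for name, b in self.named_buffers():
            state["buffer." + name] = np.array(b, copy=True)
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.array(state["param." + name], dtype=np.float32)
        for name, b in self.named_buffers():
            src = state["buffer." + name]
            arr = np.asarray(b)
            arr[...] = src
        return self

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1, shape-preserving convolution (padding = dilation*(k-1)/2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 dilation: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        if x.shape[3] != self.in_channels:
            raise ValueError(
                f"Conv2d: expected {self.in_channels} input channels, received {x.shape[3]}")
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel = kernel
        self.weight = Parameter(kaiming_uniform(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ag.depthwise_conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(kaiming_uniform(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gain = Parameter(np.ones(channels, dtype=np.float32))
        self.offset = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        return ag.batch_norm(x, self.gain, self.offset, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class LayerNormChannels(Module):
    """Normalizes over the channel axis independently at each spatial location."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.gain = Parameter(np.ones(channels, dtype=np.float32))
        self.offset = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        return ag.layer_norm_channels(x, self.gain, self.offset, self.eps)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class GELU(Module):
    def forward(self, x):
        return ag.gelu(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2x2(Module):
    def forward(self, x):
        return ag.maxpool2x2(x)


class AvgPool2x2(Module):
    def forward(self, x):
        return ag.avgpool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return ag.upsample_bilinear2x(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x
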