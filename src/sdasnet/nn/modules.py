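"""Layer objects over the autodiff primitives.

Modules own their parameters (seeded at construction from a
``numpy.random.Generator``), expose ``parameters()`` /
``named_parameters()`` for the optimizer and checkpointing, and have a
train/eval switch that only batch normalisation consults.
"""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        """Yield this module and all descendants, depth first."""
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

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

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield (prefix + name, getattr(self, name))
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data[...] = value
            elif key in bufs:
                bufs[key][...] = value
            else:
                raise KeyError(f"unexpected key {key}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=1, padding=0, dilation=1, bias=True, dtype=np.float32):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(_he_normal(rng, (out_channels, in_channels, k, k),
                                        fan_in, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel_size, rng, stride=1, padding=None,
                 dilation=1, bias=True, dtype=np.float32):
        super().__init__()
        k = kernel_size
        if padding is None:
            padding = (k - 1) * dilation // 2
        self.weight = Tensor(_he_normal(rng, (channels, k, k), k * k, dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.dilation)


class SeparableConv2d(Module):
    """Depth-wise spatial convolution followed by 1x1 point-wise mixing."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 bias=True, dtype=np.float32):
        super().__init__()
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, rng,
                                         bias=False, dtype=dtype)
        self.pointwise = Conv2d(in_channels, out_channels, 1, rng, bias=bias,
                                dtype=dtype)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class TokenProjection(Module):
    """1x1 depth-wise separable projection on token matrices (..., n_p, C).

    Depth-wise part: one scalar per input channel; point-wise part: a dense
    C_in x C_out channel-mixing applied per token.
    """

    def __init__(self, in_channels, out_channels, rng, bias=True, dtype=np.float32):
        super().__init__()
        self.dw_weight = Tensor(np.ones(in_channels, dtype=dtype), requires_grad=True)
        self.pw_weight = Tensor(
            _he_normal(rng, (in_channels, out_channels), in_channels, dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, t):
        out = F.matmul(t * self.dw_weight, self.pw_weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ChannelConv1d(Module):
    """Shared 1-D convolution along the channel axis (last axis of input)."""

    def __init__(self, kernel_size, rng, bias=True, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("channel conv kernel must be odd")
        self.weight = Tensor(_he_normal(rng, (kernel_size,), kernel_size, dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros((), dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x):
        return F.channel_conv1d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1, 1), dtype=dtype)
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))
        self.eps, self.momentum = eps, momentum
        self._axes = (0, 2, 3)

    def forward(self, x):
        if self.training:
            m = F.mean(x, self._axes, keepdims=True)
            d = x - m
            v = F.mean(d * d, self._axes, keepdims=True)
            self.running_mean += self.momentum * (m.data - self.running_mean)
            self.running_var += self.momentum * (v.data - self.running_var)
            xhat = d * F.power(v + Tensor(np.asarray(self.eps, dtype=x.dtype)), -0.5)
        else:
            scale = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(scale)
        return self.gamma * xhat + self.beta


class TokenBatchNorm(BatchNorm2d):
    """Batch normalisation over the channel axis of (N, n_p, C) tokens."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__(channels, eps, momentum, dtype)
        self.gamma = Tensor(np.ones((1, 1, channels), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, 1, channels), dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros((1, 1, channels), dtype=dtype)
        self.running_var = np.ones((1, 1, channels), dtype=dtype)
        self._axes = (0, 1)


class LayerNorm(Module):
    """Normalisation over the last axis (per-token across channels)."""

    def __init__(self, channels, eps=1e-6, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        m = F.mean(x, -1, keepdims=True)
        d = x - m
        v = F.mean(d * d, -1, keepdims=True)
        xhat = d * F.power(v + Tensor(np.asarray(self.eps, dtype=x.dtype)), -0.5)
        return self.gamma * xhat + self.beta


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)
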