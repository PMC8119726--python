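"""Layer objects over the autograd primitives.

A :class:`Module` owns named parameters (trainable) and buffers
(non-trainable running statistics) and can serialize its state to a flat
``name -> array`` dict, which round-trips through ``numpy.savez``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "resize_matrix",
    "pool_matrix",
    "BilinearResize",
    "AdaptiveAvgPool2d",
]


class Module:
    """Base class: parameter/buffer registry with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        object.__setattr__(self, key, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._buffers[name] = arr
        return arr

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        """Total count of trainable scalars (weights, biases, BN scale/shift)."""
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"checkpoint/model mismatch for {name}: "
                        f"{value.shape} vs {params[name].data.shape}")
                params[name].data = np.asarray(value, dtype=np.float64)
            else:
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """'Same'-padded 3x3 (or 1x1) convolution with optional dilation.

    He-normal weight initialization; bias is optional because the pyramid
    bottleneck convolutions are bias-free (the following BN shift absorbs it).
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1,
                 bias=True, rng=None):
        super().__init__()
        if dilation < 1:
            raise ValueError("dilation rate must be >= 1")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = self.register_parameter("weight", w)
        self.bias = self.register_parameter("bias", np.zeros(out_channels)) \
            if bias else None
        self.dilation = dilation
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training,
                               self.momentum, self.eps)


class ConvBNReLU(Module):
    """The network's standard block: convolution + batch norm + ReLU."""

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1,
                 bias=True, rng=None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, dilation,
                           bias=bias, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


def resize_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Bilinear interpolation weights (align_corners=False convention).

    Output sample i reads the continuous coordinate (i+0.5)*in/out - 0.5 of
    the input, linearly interpolating its two neighbours with edge clamping.
    """
    m = np.zeros((out_size, in_size))
    scale = in_size / out_size
    for i in range(out_size):
        src = (i + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), in_size - 1)
        i1c = min(max(i0 + 1, 0), in_size - 1)
        m[i, i0c] += 1.0 - t
        m[i, i1c] += t
    return m

def pool_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Adaptive average-pooling weights: output bin i averages input rows
    [floor(i*in/out), ceil((i+1)*in/out)).  out=1 is global average pooling."""
    m = np.zeros((out_size, in_size))
    for i in range(out_size):
        lo = int(np.floor(i * in_size / out_size))
        hi = int(np.ceil((i + 1) * in_size / out_size))
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


class BilinearResize(Module):
    """Resize to a fixed (H, W) or by an integer scale factor."""

    def __init__(self, size=None, scale=None):
        super().__init__()
        if (size is None) == (scale is None):
            raise ValueError("specify exactly one of size or scale")
        self.size = size
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        ho, wo = self.size if self.size else (h * self.scale, w * self.scale)
        return ag.linmap2d(x, resize_matrix(ho, h), resize_matrix(wo, w))


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size: int):
        super().__init__()
        self.output_size = output_size

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        s = self.output_size
        return ag.linmap2d(x, pool_matrix(s, h), pool_matrix(s, w))
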