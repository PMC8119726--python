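"""Reusable computational units: dilated convolution and pyramid pooling.

Dilated (atrous) convolution spaces the taps of a k x k kernel ``r`` pixels
apart, so a 3x3 kernel at rate r covers a (2^(r+1) - 1)-pixel-wide receptive
field without adding parameters.  The pyramid pooling module (PPM) pools a
feature map to N output sizes (largest ~ the dataset-specific max scale,
smallest 1x1 = global average pooling), bottlenecks each pooled map with a
1x1 convolution, bilinearly upsamples back, and concatenates everything with
the original features to fuse multi-scale global context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as ag

__all__ = [
    "DilatedConvSpec",
    "PPMSpec",
    "dilated_convolve",
    "receptive_field_side",
    "ppm_forward",
    "PyramidPooling",
]


@dataclass
class DilatedConvSpec:
    """Configuration of one dilated convolution layer."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    dilation_rate: int = 1
    with_batchnorm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        if self.activation not in ("relu", "none"):
            raise ValueError("activation must be 'relu' or 'none'")


@dataclass
class PPMSpec:
    """Configuration of a pyramid pooling module."""

    in_channels: int
    pooled_sizes: list[int] = field(default_factory=lambda: [64, 21, 4, 1])
    bottleneck_channels_per_level: int | None = None
    pooling: str = "average"

    def __post_init__(self):
        sizes = list(self.pooled_sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("pooled sizes must be positive")
        if sorted(sizes, reverse=True) != sizes or len(set(sizes)) != len(sizes):
            raise ValueError("pooled_sizes must be strictly decreasing")
        if sizes[-1] != 1:
            raise ValueError("smallest pyramid level must be 1 (global pooling)")
        if self.pooling != "average":
            raise ValueError("only average pooling is supported")
        if self.bottleneck_channels_per_level is None:
            # default 1/N reduction of the context dimension
            self.bottleneck_channels_per_level = max(
                self.in_channels // len(sizes), 1)
        if self.bottleneck_channels_per_level < 1:
            raise ValueError("bottleneck channels must be positive")

    @property
    def num_levels(self) -> int:
        return len(self.pooled_sizes)

    @property
    def out_channels(self) -> int:
        return self.in_channels + self.num_levels * self.bottleneck_channels_per_level


def receptive_field_side(r: int) -> int:
    """Side length (pixels) of the receptive field of a 3x3 convolution at
    dilation rate ``r``: 2^(r+1) - 1.  r=1 gives the standard 3x3 field."""
    if int(r) != r or r < 1:
        raise ValueError("dilation rate must be an integer >= 1")
    return 2 ** (int(r) + 1) - 1


def _convolve_1d(f: np.ndarray, w: np.ndarray, r: int) -> np.ndarray:
    """True discrete convolution with an odd, centered, r-dilated kernel."""
    k = w.shape[0]
    c = k // 2
    out = np.zeros_like(f, dtype=np.float64)
    n = f.shape[0]
    for j in range(k):
        shift = -r * (j - c)  # true convolution: out[x] += w[j] * f[x - r(j-c)]
        src_lo, src_hi = max(0, -shift), min(n, n - shift)
        if src_lo < src_hi:
            out[src_lo:src_hi] += w[j] * f[src_lo + shift: src_hi + shift]
    return out


def dilated_convolve(feature_map: np.ndarray, spec: DilatedConvSpec,
                     weights: np.ndarray) -> np.ndarray:
    """Dilated convolution of a feature map with explicit kernel weights.

    2-D input is H x W x C_in with ``weights`` shaped (k, k, C_in, C_out);
    output is H x W x C_out (zero padding preserves the spatial size).  A
    1-D signal with a 1-D kernel is also accepted for the scalar form of the
    operator.  The kernel is centered and true-convolution oriented, so an
    impulse input returns the kernel spread with r - 1 zeros between taps;
    rate 1 reduces to standard convolution.
    """
    f = np.asarray(feature_map, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    r = spec.dilation_rate
    if f.ndim == 1 and w.ndim == 1:
        if w.shape[0] != spec.kernel_size:
            raise ValueError("kernel length does not match spec.kernel_size")
        out = _convolve_1d(f, w, r)
    elif f.ndim == 3 and w.ndim == 4:
        h, wd, cin = f.shape
        if cin != spec.in_channels:
            raise ValueError(
                f"input has {cin} channels, spec expects {spec.in_channels}")
        k = spec.kernel_size
        if w.shape != (k, k, spec.in_channels, spec.out_channels):
            raise ValueError(f"weights must be shaped {(k, k, cin, spec.out_channels)}")
        c = k // 2
        p = r * c
        fp = np.pad(f, ((p, p), (p, p), (0, 0)))
        out = np.zeros((h, wd, spec.out_channels))
        for i in range(k):
            for j in range(k):
                # true convolution: output reads input at -r*(tap - center)
                patch = fp[p - r * (i - c): p - r * (i - c) + h,
                           p - r * (j - c): p - r * (j - c) + wd]
                out += patch @ w[i, j]
    else:
        raise ValueError("expected 1-D signal + 1-D kernel, or HWC map + 4-D kernel")
    if spec.activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def ppm_forward(features: np.ndarray, spec: PPMSpec,
                kernels: list[np.ndarray] | None = None,
                return_branches: bool = False):
    """Pure-NumPy pyramid pooling forward pass on an H x W x C feature map.

    Per pyramid level: adaptive average pooling to ``s x s``, 1x1 convolution
    (``kernels[i]`` shaped (C, bottleneck); identity-free default is a seeded
    random projection), bilinear upsampling back to H x W.  Output channels
    are C + N * bottleneck.
    """
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 3 or f.shape[2] != spec.in_channels:
        raise ValueError(f"features must be H x W x {spec.in_channels}")
    h, w, c = f.shape
    if max(spec.pooled_sizes) > min(h, w):
        raise ValueError(
            f"pooled size {max(spec.pooled_sizes)} exceeds input side {min(h, w)}")
    b = spec.bottleneck_channels_per_level
    if kernels is None:
        rng = np.random.default_rng(0)
        kernels = [rng.normal(0, 1.0 / np.sqrt(c), size=(c, b))
                   for _ in spec.pooled_sizes]
    branches = []
    for s, kmat in zip(spec.pooled_sizes, kernels):
        kmat = np.asarray(kmat, dtype=np.float64)
        if kmat.shape != (c, b):
            raise ValueError(f"1x1 kernel must be shaped {(c, b)}")
        pr, pc = nn.pool_matrix(s, h), nn.pool_matrix(s, w)
        pooled = np.einsum("ph,hwc->pwc", pr, f)
        pooled = np.einsum("qw,pwc->pqc", pc, pooled)
        projected = pooled @ kmat
        ur, uc = nn.resize_matrix(h, s), nn.resize_matrix(w, s)
        up = np.einsum("hp,pqc->hqc", ur, projected)
        up = np.einsum("wq,hqc->hwc", uc, up)
        branches.append(up)
    out = np.concatenate([f] + branches, axis=2)
    if return_branches:
        return out, branches
    return out


class PyramidPooling(nn.Module):
    """PPM as a trainable network module (NCHW tensors).

    Each branch: adaptive average pool -> bias-free 1x1 convolution -> BN ->
    ReLU -> bilinear upsample to the input size; output is the channel
    concatenation of the input with all branches.
    """

    def __init__(self, in_channels: int, bottleneck_channels: int,
                 pooled_sizes, rng=None):
        super().__init__()
        self.pooled_sizes = list(pooled_sizes)
        self.in_channels = in_channels
        self.bottleneck_channels = bottleneck_channels
        for i, _s in enumerate(self.pooled_sizes):
            setattr(self, f"conv{i}",
                    nn.Conv2d(in_channels, bottleneck_channels, kernel_size=1,
                              bias=False, rng=rng))
            setattr(self, f"bn{i}", nn.BatchNorm2d(bottleneck_channels))

    @property
    def out_channels(self) -> int:
        return self.in_channels + len(self.pooled_sizes) * self.bottleneck_channels

    def forward(self, x):
        _, _, h, w = x.data.shape
        outs = [x]
        for i, s in enumerate(self.pooled_sizes):
            pooled = ag.linmap2d(x, nn.pool_matrix(s, h), nn.pool_matrix(s, w))
            y = getattr(self, f"conv{i}")(pooled)
            y = ag.relu(getattr(self, f"bn{i}")(y))
            y = ag.linmap2d(y, nn.resize_matrix(h, s), nn.resize_matrix(w, s))
            outs.append(y)
        return ag.concat(outs, axis=1)
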