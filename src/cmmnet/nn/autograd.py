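"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation networks in this package are small, fixed directed acyclic
graphs, so a tape-based scalar-loss autograd over whole-array operations is
all that is needed.  Each op records its parents and a closure that
accumulates gradients into them; :meth:`Tensor.backward` walks the tape in
reverse topological order.

Array convention is NCHW (batch, channels, height, width) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batch_norm2d",
    "relu",
    "max_pool2d",
    "linmap2d",
    "concat",
    "softmax_channels",
    "select_channel",
    "soft_dice_loss",
]


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data, parents, backward):
    out = Tensor(data)
    track = any(p.requires_grad or p._parents for p in parents)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False
    return out


def _same_pad(k, dilation):
    # effective extent (k-1)*d + 1; symmetric zero padding for odd k
    return dilation * (k - 1) // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """'Same'-padded 2-D cross-correlation with kernel dilation.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, k, k), k odd; ``b``: (Cout,) or None.
    Dilation r samples kernel taps r pixels apart, enlarging the receptive
    field without extra parameters; r=1 is a standard convolution layer.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, kernel expects {cin_w}")
    if kh != kw or kh % 2 == 0:
        raise ValueError("kernel must be square with odd size")
    if dilation < 1:
        raise ValueError("dilation rate must be >= 1")
    p = _same_pad(kh, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((n, cout, h, wd))
    for ki in range(kh):
        for kj in range(kw):
            patch = xp[:, :, ki * dilation: ki * dilation + h,
                       kj * dilation: kj * dilation + wd]
            out += np.einsum("oi,nihw->nohw", w.data[:, :, ki, kj], patch,
                             optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad or x.requires_grad or x._parents:
            gxp = np.zeros_like(xp) if (x.requires_grad or x._parents) else None
            for ki in range(kh):
                for kj in range(kw):
                    patch = xp[:, :, ki * dilation: ki * dilation + h,
                               kj * dilation: kj * dilation + wd]
                    if w.requires_grad:
                        gw = np.einsum("nohw,nihw->oi", g, patch, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, ki, kj] += gw
                    if gxp is not None:
                        gxp[:, :, ki * dilation: ki * dilation + h,
                            kj * dilation: kj * dilation + wd] += np.einsum(
                            "oi,nohw->nihw", w.data[:, :, ki, kj], g,
                            optimize=True)
            if gxp is not None:
                gx = gxp[:, :, p: p + h, p: p + wd] if p else gxp
                x._accumulate(gx)
        if b is not None and b.requires_grad:
            if b.grad is None:
                b.grad = np.zeros_like(b.data)
            b.grad += g.sum(axis=(0, 2, 3))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            if gamma.grad is None:
                gamma.grad = np.zeros_like(gamma.data)
            gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        if beta.requires_grad:
            if beta.grad is None:
                beta.grad = np.zeros_like(beta.data)
            beta.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad or x._parents:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gxhat.sum(axis=(0, 2, 3))
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3))
                gx = (gxhat - (s1[None, :, None, None]
                               + xhat * s2[None, :, None, None]) / m) \
                    * inv[None, :, None, None]
            else:
                gx = gxhat * inv[None, :, None, None]
            x._accumulate(gx)

    return _node(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _node(out, (x,), backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gf = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(n, c, h, w))

    return _node(out, (x,), backward)


def linmap2d(x: Tensor, mr: np.ndarray, mc: np.ndarray) -> Tensor:
    """Separable linear map over the spatial axes: y = Mr @ x @ Mc^T.

    A single primitive covers both adaptive average pooling (bin-averaging
    rows) and bilinear interpolation (interpolation-weight rows); its adjoint
    gives the exact backward pass.
    """
    y = np.einsum("ph,nchw->ncpw", mr, x.data, optimize=True)
    y = np.einsum("qw,ncpw->ncpq", mc, y, optimize=True)

    def backward(g):
        gx = np.einsum("ph,ncpq->nchq", mr, g, optimize=True)
        gx = np.einsum("qw,nchq->nchw", mc, gx, optimize=True)
        x._accumulate(gx)

    return _node(y, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(out, tuple(tensors), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis, pixelwise."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accumulate(p * (g - dot))

    return _node(p, (x,), backward)


def select_channel(x: Tensor, idx: int) -> Tensor:
    out = x.data[:, idx]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, idx] = g
        x._accumulate(gx)

    return _node(out, (x,), backward)


def soft_dice_loss(prob_fg: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft dice loss L = 1 - (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps).

    ``prob_fg``: (N, H, W) foreground probabilities; ``target``: matching
    binary array.  The per-sample losses are averaged over the batch.  On a
    binarized prediction this is exactly 1 - DSC (up to eps).
    """
    t = np.asarray(target, dtype=np.float64)
    if t.shape != prob_fg.data.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {prob_fg.data.shape}")
    axes = tuple(range(1, t.ndim))
    inter = (prob_fg.data * t).sum(axis=axes)
    denom = prob_fg.data.sum(axis=axes) + t.sum(axis=axes) + eps
    num = 2.0 * inter + eps
    per_sample = 1.0 - num / denom
    out = per_sample.mean(keepdims=False)

    def backward(g):
        n = t.shape[0]
        shape = (n,) + (1,) * (t.ndim - 1)
        gp = -(2.0 * t * denom.reshape(shape) - num.reshape(shape)) \
            / denom.reshape(shape) ** 2
        prob_fg._accumulate(g * gp / n)

    return _node(np.asarray(out), (prob_fg,), backward)
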