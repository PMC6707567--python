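"""Minimal reverse-mode autodiff over numpy arrays.

Only the operations needed by the segmentation networks are provided:
elementwise arithmetic, ReLU/sigmoid, strided/dilated 2-D convolution with
TensorFlow-style SAME padding, batch normalization, nearest-neighbour
upsampling, channel concatenation and a fused soft-Dice loss.

Activations are NHWC float32 (channels last); convolution kernels are HWIO
(kh, kw, in_channels, out_channels).  Channels-last keeps the inner GEMM
operands contiguous, which is what makes CPU training viable here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "conv2d",
    "batch_norm",
    "upsample_nearest",
    "concat_channels",
    "soft_dice_loss",
    "same_pad_amounts",
]


class Tensor:
    """An array node in the autodiff graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :meth:`backward` is called on a scalar descendant.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # Convenience operators (used sparingly; heavy ops are free functions).
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # numerically stable logistic
    data = np.empty_like(x.data)
    pos = x.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def same_pad_amounts(size: int, kernel: int, stride: int, dilation: int):
    """SAME-padding (begin, end) so that output size = ceil(size / stride)."""
    eff = dilation * (kernel - 1) + 1
    out = -(-size // stride)
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, dilation: int = 1) -> Tensor:
    """SAME-padded 2-D cross-correlation.

    x: (N, H, W, C); w: (kh, kw, C, F); b: (F,) or None.
    Output spatial size is ceil(input / stride) in each dimension.
    Implemented as one GEMM per kernel offset so the operands stay
    contiguous in memory.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    n, h, wd, c = x.shape
    kh, kw, c2, f = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {c2}")
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    s, d = stride, dilation
    ph = same_pad_amounts(h, kh, s, d)
    pw = same_pad_amounts(wd, kw, s, d)
    xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
    ho, wo = -(-h // s), -(-wd // s)

    out = np.zeros((n * ho * wo, f), dtype=np.float32)
    w2 = w.data.reshape(kh * kw, c, f)
    slices = []
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i * d: i * d + s * ho: s, j * d: j * d + s * wo: s, :]
            slices.append(sl)
            out += sl.reshape(-1, c) @ w2[i * kw + j]
    out = out.reshape(n, ho, wo, f)
    if b is not None:
        out += b.data

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(-1, f)
        if w.requires_grad or w._parents:
            gw = np.empty_like(w.data)
            for idx in range(kh * kw):
                gw[idx // kw, idx % kw] = slices[idx].reshape(-1, c).T @ g2
            w._accumulate(gw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = (g2 @ w2[i * kw + j].T).reshape(n, ho, wo, c)
                    gxp[:, i * d: i * d + s * ho: s,
                        j * d: j * d + s * wo: s, :] += contrib
            x._accumulate(gxp[:, ph[0]: ph[0] + h, pw[0]: pw[0] + wd, :])

    return _make(out, (x, w) if b is None else (x, w, b), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.9,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in inference mode the running buffers are used.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 1, 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * inv_std
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gs = gamma.data * inv_std
            if training:
                gm = g.mean(axis=axes)
                gxh = (g * xhat).mean(axis=axes)
                x._accumulate(gs * (g - gm - xhat * gxh))
            else:
                x._accumulate(gs * g)

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    x = _as_tensor(x)
    data = x.data.repeat(factor, axis=1).repeat(factor, axis=2)
    n, h, w, c = x.shape

    def backward(g):
        gr = g.reshape(n, h, factor, w, factor, c).sum(axis=(2, 4))
        x._accumulate(gr)

    return _make(data, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=-1)
    sizes = [t.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._accumulate(np.ascontiguousarray(g[..., lo:hi]))

    return _make(data, tuple(tensors), backward)


def soft_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice between a probability map and a binary target.

    Pooled over the whole batch: loss = 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s).
    """
    pred = _as_tensor(pred)
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.shape:
        raise ValueError(f"target shape {t.shape} != prediction shape {pred.shape}")
    inter = float((pred.data * t).sum())
    denom = float(pred.data.sum() + t.sum()) + smooth
    num = 2.0 * inter + smooth
    loss = 1.0 - num / denom

    def backward(g):
        # d/dp [num/denom] = (2*t*denom - num) / denom^2
        gp = -(2.0 * t * denom - num) / (denom * denom)
        pred._accumulate(g * gp)

    return _make(np.float32(loss), (pred,), backward)
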