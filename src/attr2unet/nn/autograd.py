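"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by an encoder–decoder segmentation network are
provided: 2-D cross-correlation ("convolution" in deep-learning usage, stride 1),
batch normalization, ReLU/sigmoid, 2x2 max pooling, 2x nearest-neighbour
upsampling, channel concatenation, broadcast add/multiply, reductions and a
fused binary cross-entropy. Gradients are accumulated by a topological sweep
over the recorded tape.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "scale",
    "neg",
    "relu",
    "sigmoid",
    "conv2d",
    "batch_norm2d",
    "max_pool2d",
    "upsample_nearest2d",
    "concat_channels",
    "dropout",
    "mean_all",
    "sum_all",
    "binary_cross_entropy",
]


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None,
    ):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward
        self.grad: Optional[np.ndarray] = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node; `grad` defaults to ones (scalar loss)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        # Iterative post-order DFS to avoid recursion limits on deep graphs.
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # Leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that requires gradients (a learnable weight)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = g.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, _parents=(a, b), _backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g):
        return _unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)

    return Tensor(out, _parents=(a, b), _backward=bwd)


def scale(a: Tensor, s: float) -> Tensor:
    out = a.data * s

    def bwd(g):
        return (g * s,)

    return Tensor(out, _parents=(a,), _backward=bwd)


def neg(a: Tensor) -> Tensor:
    return scale(a, -1.0)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = a.data * mask

    def bwd(g):
        return (g * mask,)

    return Tensor(out, _parents=(a,), _backward=bwd)


def sigmoid(a: Tensor) -> Tensor:
    # Numerically stable logistic.
    x = a.data
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = out.astype(x.dtype)

    def bwd(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, _parents=(a,), _backward=bwd)


# ---------------------------------------------------------------------------
# Convolution (stride 1, symmetric zero padding)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _corr(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation of (N,C,H,W) with (O,C,kh,kw)."""
    o, c, kh, kw = w.shape
    n = x.shape[0]
    if kh == 1 and kw == 1:
        xm = x.reshape(n, c, -1)
        out = np.matmul(w.reshape(o, c), xm)  # (N, O, H*W) by broadcasting
        return out.reshape(n, o, x.shape[2], x.shape[3])
    xp = _pad_hw(x, pad)
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    return np.einsum("nchwij,ocij->nohw", view, w, optimize=True)


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1. weight: (out_c, in_c, kh, kw)."""
    o, c, kh, kw = weight.data.shape
    if x.data.shape[1] != c:
        raise ValueError(f"channel mismatch: input has {x.data.shape[1]} channels, weight expects {c}")
    out = _corr(x.data, weight.data, padding)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)
    n = x.data.shape[0]

    def bwd(g):
        gw = None
        if weight.requires_grad:
            if kh == 1 and kw == 1:
                gw = np.einsum("nohw,nchw->oc", g, x.data, optimize=True).reshape(weight.data.shape)
            else:
                xp = _pad_hw(x.data, padding)
                view = sliding_window_view(xp, (kh, kw), axis=(2, 3))
                gw = np.einsum("nohw,nchwij->ocij", g, view, optimize=True)
        gx = None
        if x.requires_grad:
            # Full correlation of g with spatially-flipped, channel-swapped weights.
            w_rot = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx = _corr(g, np.ascontiguousarray(w_rot), kh - 1 - padding)
        gb = g.sum(axis=(0, 2, 3)) if bias is not None and bias.requires_grad else None
        if bias is None:
            return gx, gw
        return gx, gw, gb

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=bwd)


# ---------------------------------------------------------------------------
# Batch normalization over (N, H, W) per channel
# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    training: bool,
) -> Tensor:
    """Normalize per channel with the supplied statistics.

    In training mode `mean`/`var` are the current mini-batch statistics (biased
    variance) and the full batch-norm gradient is used; in eval mode they are
    frozen running statistics treated as constants.
    """
    c = x.data.shape[1]
    mean = mean.reshape(1, c, 1, 1)
    inv_std = 1.0 / np.sqrt(var.reshape(1, c, 1, 1) + eps)
    xhat = (x.data - mean) * inv_std
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bwd(g):
        gg = (g * xhat).sum(axis=(0, 2, 3)) if gamma.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if beta.requires_grad else None
        gx = None
        if x.requires_grad:
            gw = gamma.data.reshape(1, c, 1, 1) * inv_std
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True) / m
                gxhat_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                gx = gw * (g - gsum - xhat * gxhat_sum)
            else:
                gx = gw * g
        return gx, gg, gb

    return Tensor(out.astype(x.data.dtype), _parents=(x, gamma, beta), _backward=bwd)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d requires even spatial dims, got {h}x{w}")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (gx,)

    return Tensor(np.ascontiguousarray(out), _parents=(x,), _backward=bwd)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    n, c, h, w = x.data.shape

    def bwd(g):
        gx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        return (gx,)

    return Tensor(out, _parents=(x,), _backward=bwd)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=1))

    return Tensor(out, _parents=tuple(tensors), _backward=bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or when p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = x.data * keep

    def bwd(g):
        return (g * keep,)

    return Tensor(out, _parents=(x,), _backward=bwd)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values to [lo, hi]; the gradient is zero where clipping is active."""
    inside = (x.data > lo) & (x.data < hi)
    out = np.clip(x.data, lo, hi)

    def bwd(g):
        return (g * inside,)

    return Tensor(out, _parents=(x,), _backward=bwd)


def sum_all(x: Tensor) -> Tensor:
    out = np.asarray(x.data.sum(), dtype=x.data.dtype)

    def bwd(g):
        return (np.broadcast_to(g, x.data.shape).astype(x.data.dtype),)

    return Tensor(out, _parents=(x,), _backward=bwd)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size
    out = np.asarray(x.data.mean(), dtype=x.data.dtype)

    def bwd(g):
        return (np.broadcast_to(g / n, x.data.shape).astype(x.data.dtype),)

    return Tensor(out, _parents=(x,), _backward=bwd)


def binary_cross_entropy(pred: Tensor, target: np.ndarray, clip: float = 1e-7) -> Tensor:
    """Mean per-pixel negative log-likelihood, fused forward/backward.

    Predictions are clipped to [clip, 1-clip]; the gradient is zero where
    clipping is active (the clip is flat there).
    """
    target = np.asarray(target)
    if pred.data.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {target.shape}")
    p = np.clip(pred.data, clip, 1.0 - clip)
    inside = (pred.data > clip) & (pred.data < 1.0 - clip)
    n = p.size
    loss = -(target * np.log(p) + (1.0 - target) * np.log1p(-p)).mean()

    def bwd(g):
        gp = g * inside * (p - target) / (p * (1.0 - p) * n)
        return (gp.astype(pred.data.dtype),)

    return Tensor(np.asarray(loss, dtype=pred.data.dtype), _parents=(pred,), _backward=bwd)
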