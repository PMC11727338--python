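"""Compact reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set a small encoder–decoder CNN needs:
same-padded stride-1 convolution (via im2col / ``sliding_window_view``),
ReLU, logistic sigmoid, window max/average pooling, nearest-neighbour
upsampling, channel concatenation, elementwise add/multiply, and a
clipped binary cross-entropy reduction.  Tensors are NCHW ``float64``;
gradients are accumulated by topological-order backpropagation from a
scalar loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A NumPy array plus optional gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big images
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- convolution

def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 zero-padded 'same' correlation, odd kernels only."""
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,O
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


def _conv_weight_grad(x: np.ndarray, gy: np.ndarray, kshape) -> np.ndarray:
    kh, kw = kshape[2], kshape[3]
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    # gy: N,O,H,W  ->  O,C,kh,kw
    return np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution; weight (O,C,kh,kw), odd kernel."""
    if x.data.shape[1] != weight.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {weight.data.shape[1]}"
        )
    y = _conv_same(x.data, weight.data)
    if bias is not None:
        y += bias.data[None, :, None, None]

    def backward(gy):
        gx = gw = gb = None
        if x.requires_grad:
            w_rot = np.ascontiguousarray(
                weight.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            )
            gx = _conv_same(gy, w_rot)
        if weight.requires_grad:
            gw = _conv_weight_grad(x.data, gy, weight.data.shape)
        if bias is not None and bias.requires_grad:
            gb = gy.sum(axis=(0, 2, 3))
        return (gx, gw, gb)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(y, parents, backward)


# ------------------------------------------------------------- pointwise ops

def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def backward(gy):
        return (gy * (x.data > 0.0),)

    return _node(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data)

    def backward(gy):
        return (gy * y * (1.0 - y),)

    return _node(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add: shape mismatch")

    def backward(gy):
        return (gy, gy)

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("mul: shape mismatch")

    def backward(gy):
        return (gy * b.data, gy * a.data)

    return _node(a.data * b.data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    y = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(gy):
        sl = [slice(None)] * gy.ndim
        grads = []
        for i in range(len(sizes)):
            sl[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(gy[tuple(sl)])
        return tuple(grads)

    return _node(y, tuple(tensors), backward)


# --------------------------------------------------------- pooling / resizing

def _check_divisible(x: Tensor, k: int) -> None:
    _, _, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool factor {k}")


def maxpool2d(x: Tensor, k: int) -> Tensor:
    _check_divisible(x, k)
    n, c, h, w = x.data.shape
    xr = (
        x.data.reshape(n, c, h // k, k, w // k, k)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // k, w // k, k * k)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(gy):
        g = np.zeros((n, c, h // k, w // k, k * k))
        np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
        g = (
            g.reshape(n, c, h // k, w // k, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        return (g,)

    return _node(y, (x,), backward)


def avgpool2d(x: Tensor, k: int) -> Tensor:
    _check_divisible(x, k)
    n, c, h, w = x.data.shape
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(gy):
        g = np.broadcast_to(
            gy[:, :, :, None, :, None] / (k * k), (n, c, h // k, k, w // k, k)
        )
        return (g.reshape(n, c, h, w),)

    return _node(y, (x,), backward)


def upsample_nearest(x: Tensor, f: int) -> Tensor:
    n, c, h, w = x.data.shape
    y = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(gy):
        return (gy.reshape(n, c, h, f, w, f).sum(axis=(3, 5)),)

    return _node(y, (x,), backward)


# -------------------------------------------------------------------- losses

def bce(probs: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probability clipping to [eps, 1-eps]."""
    t = np.asarray(target, dtype=np.float64)
    if t.shape != probs.data.shape:
        raise ValueError("bce: target shape mismatch")
    p = np.clip(probs.data, eps, 1.0 - eps)
    loss = -np.mean(t * np.log(p) + (1.0 - t) * np.log1p(-p))
    inside = (probs.data > eps) & (probs.data < 1.0 - eps)

    def backward(gy):
        g = (-(t / p) + (1.0 - t) / (1.0 - p)) / t.size
        return (gy * g * inside,)

    return _node(loss, (probs,), backward)
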