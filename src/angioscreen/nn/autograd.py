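"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: just the operations the angiography models need
(dense/conv/pool layers, recurrent cells, sigmoid/softmax losses). Tensors hold
single-precision data; gradients are accumulated by a topological backward
sweep.
"""

from __future__ import annotations

import numpy as np

#: Engine dtype: single precision — the desk-scale models are noise-tolerant
#: and single precision roughly doubles conv/matmul throughput on one CPU.
DTYPE = np.float32

__all__ = ["Tensor", "concatenate", "conv2d", "maxpool2d", "global_avg_pool",
           "softmax_cross_entropy", "bce_with_logits", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        out._backward = backward
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0), )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y ** 2),)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    # --------------------------------------------------------------- reshape
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: (g.transpose(*inv),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad and g is not None:
                    # first contribution is assigned, later ones accumulate
                    # out-of-place (g may alias another node's buffer)
                    p.grad = g if p.grad is None else p.grad + g
        for t in topo:
            if t.grad is None:
                t.grad = np.zeros_like(t.data)


# ----------------------------------------------------------------- functions
def concatenate(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0)[i] for i in range(len(tensors)))

    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; `w` has shape (cout, cin, kh, kw).

    Computed as a sum of shifted channel matmuls (one tensordot per kernel
    offset), which avoids materialising im2col buffers.
    """
    cout, cin, kh, kw = w.data.shape
    n, c, h, wd = x.data.shape
    if kh == kw == 1 and stride == 1 and pad == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    y = np.zeros((n, ho, wo, cout))
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            y += np.tensordot(xs, w.data[:, :, i, j], axes=([1], [1]))
    if b is not None:
        y += b.data
    out = Tensor(y.transpose(0, 3, 1, 2),
                 parents=(x, w) if b is None else (x, w, b))

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))   # (N, Ho, Wo, cout)
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                dw[:, :, i, j] = np.tensordot(gt, xs, axes=([0, 1, 2], [0, 2, 3]))
                dxs = np.tensordot(gt, w.data[:, :, i, j], axes=([3], [0]))
                dxp[:, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += dxs.transpose(0, 3, 1, 2)
        dx = dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp
        if b is None:
            return dx, dw
        return dx, dw, gt.sum(axis=(0, 1, 2))

    out._backward = backward
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a single channel matmul."""
    wm = w.data[:, :, 0, 0]                              # (cout, cin)
    y = np.tensordot(x.data, wm, axes=([1], [1]))        # (N, H, W, cout)
    if b is not None:
        y += b.data
    out = Tensor(y.transpose(0, 3, 1, 2),
                 parents=(x, w) if b is None else (x, w, b))

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
        dw = np.tensordot(gt, x.data, axes=([0, 1, 2], [0, 2, 3]))
        dx = np.tensordot(gt, wm, axes=([3], [0])).transpose(0, 3, 1, 2)
        if b is None:
            return dx, dw[:, :, None, None]
        return dx, dw[:, :, None, None], gt.sum(axis=(0, 1, 2))

    out._backward = backward
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by k.

    The gradient flows to the first maximal element of each window.
    """
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    r = x.data.reshape(n, c, h // k, k, w // k, k)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    idx = flat.argmax(axis=4)
    y = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
    out = Tensor(y, parents=(x,))

    def backward(g):
        gflat = np.zeros((n, c, h // k, w // k, k * k), dtype=g.dtype)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=4)
        return (gflat.reshape(n, c, h // k, w // k, k, k)
                .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w),)

    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C); gradient flows to the arg-max locations."""
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out = Tensor(flat.max(axis=2), parents=(x,))

    def backward(g):
        gflat = np.zeros((n, c, h * w))
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gflat[ii, jj, idx] = g
        return (gflat.reshape(n, c, h, w),)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels; numerically stable fused op."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        dp = p.copy()
        dp[np.arange(n), labels] -= 1.0
        return (g * dp / n,)

    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (stable log-sum-exp form)."""
    z, t = logits.data, np.asarray(targets, dtype=np.float64)
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    out = Tensor(loss, parents=(logits,))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    out._backward = lambda g: (g * (p - t) / z.size,)
    return out
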