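"""Minimal reverse-mode autodiff over numpy arrays.

Tensors are NHWC for images. Only the operations needed by the model family
are implemented: dense/conv2d (stride 1, 'same' padding), 2x2 max pooling,
nearest-neighbour x2 upsampling, channel concatenation, global average
pooling, elementwise arithmetic, relu/sigmoid/softmax/log, reductions and
inverted dropout. Gradients are accumulated into ``.grad`` by ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "upsample2x2",
           "global_avg_pool", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = _bw
        return out

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        out._prev = (self,)

        def _bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    # -- activations ------------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        out._prev = (self,)

        def _bw(g):
            self._accum(g * (self.data > 0))
        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s)
        out._prev = (self,)

        def _bw(g):
            self._accum(g * s * (1.0 - s))
        out._backward = _bw
        return out

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(p)
        out._prev = (self,)

        def _bw(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accum((g - dot) * p)
        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        out._prev = (self,)

        def _bw(g):
            self._accum(g / self.data)
        out._backward = _bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(np.float32))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, shape).astype(np.float32))
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.float32(1.0 / n))


# -- image ops -------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 'same' 2-D convolution; x NHWC, w (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.data.shape
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.data.shape
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # windows: (n, h, w, kh, kw, cin)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)
    cols = win.reshape(n * h * wd, kh * kw * cin)
    w2 = w.data.reshape(kh * kw * cin, cout)
    out_data = (cols @ w2 + b.data).reshape(n, h, wd, cout)
    out = Tensor(out_data)
    out._prev = (x, w, b)

    def _bw(g):
        g2 = g.reshape(n * h * wd, cout)
        w._accum((cols.T @ g2).reshape(w.data.shape))
        b._accum(g2.sum(axis=0))
        gcols = (g2 @ w2.T).reshape(n, h, wd, kh, kw, cin)
        gx = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gx[:, i:i + h, j:j + wd, :] += gcols[:, :, :, i, j, :]
        x._accum(gx[:, ph:ph + h, pw:pw + wd, :])
    out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial dims"
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    win = win.reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0])
    out._prev = (x,)

    def _bw(g):
        gwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gwin = gwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x._accum(gwin.reshape(n, h, w, c))
    out._backward = _bw
    return out


def upsample2x2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    out = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2))
    out._prev = (x,)
    n, h, w, c = x.data.shape

    def _bw(g):
        x._accum(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))
    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NHWC -> NC mean over spatial dims."""
    return x.mean(axis=(1, 2))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._prev = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        splits = np.cumsum(sizes)[:-1]
        for t, gp in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gp)
    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return x * Tensor(mask)
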