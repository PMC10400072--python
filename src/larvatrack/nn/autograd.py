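"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operator set needed by the posture-heatmap and
behavior-state networks: broadcasting arithmetic, matmul, elementwise
nonlinearities, reductions, reshape / concatenation / slicing, 3x3
same-padding convolution (via im2col), 2x2 max pooling, and 2x nearest
upsampling.  Gradients flow through a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d", "maxpool2d",
           "upsample2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:               # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        o = self._wrap(other)
        return Tensor._op(self.data + o.data, (self, o), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        return Tensor._op(self.data * o.data, (self, o), lambda g: (
            _unbroadcast(g * o.data, self.data.shape),
            _unbroadcast(g * self.data, o.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return Tensor._op(self.data / o.data, (self, o), lambda g: (
            _unbroadcast(g / o.data, self.data.shape),
            _unbroadcast(-g * self.data / o.data ** 2, o.data.shape)))

    def __matmul__(self, other):
        o = self._wrap(other)
        return Tensor._op(self.data @ o.data, (self, o), lambda g: (
            g @ o.data.swapaxes(-1, -2), self.data.swapaxes(-1, -2) @ g))

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor._op(self.data[idx], (self,), back)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._op(s, (self,), lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._op(t, (self,), lambda g: (g * (1 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._op(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)
        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._op(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(orig),))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis),
                      tuple(tensors), back)


def _im2col(x: np.ndarray, k: int):
    """(N, C, H, W) -> sliding (N, C, k, k, H, W) view of the padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    return np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 2-D convolution.

    ``x``: (N, C, H, W); ``w``: (O, C, k, k) with odd k; ``b``: (O,).
    """
    N, C, H, W = x.data.shape
    O, _, k, _ = w.data.shape
    cols = _im2col(x.data, k)                    # (N, C, H, W, k, k)
    out = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def back(g):
        gw = np.einsum("nohw,nchwij->ocij", g, cols, optimize=True)
        # dx: full correlation of g with w flipped over the output channel
        p = k // 2
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
        w_flip = w.data[:, :, ::-1, ::-1]
        gx = np.einsum("nohwij,ocij->nchw", gcols, w_flip, optimize=True)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)
    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._op(out, parents, back)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (input H, W must be even)."""
    N, C, H, W = x.data.shape
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    windows = r.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def back(g):
        gw = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        gx = gw.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(N, C, H, W),)
    return Tensor._op(out, (x,), back)


def upsample2d(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.data.shape

    def back(g):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)
    return Tensor._op(out, (x,), back)


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
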