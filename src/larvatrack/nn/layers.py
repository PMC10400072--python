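"""Layer building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat, conv2d

__all__ = ["Module", "Linear", "Conv2d", "LSTMCell", "ConvLSTMCell",
           "BiLSTM", "softmax", "cross_entropy"]


class Module:
    """Base class: parameter collection and recurrent-state reset."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def reset_state(self) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.reset_state()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.reset_state()


def _glorot(rng, *shape):
    fan_in = np.prod(shape[1:]) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng):
        self.w = Parameter(_glorot(rng, d_out, d_in).T)
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng):
        self.w = Parameter(_glorot(rng, c_out, c_in, k, k))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class LSTMCell(Module):
    """Standard LSTM cell; state persists across calls until reset."""

    def __init__(self, d_in: int, d_hidden: int, rng):
        self.d_hidden = d_hidden
        self.wx = Parameter(_glorot(rng, 4 * d_hidden, d_in).T)
        self.wh = Parameter(_glorot(rng, 4 * d_hidden, d_hidden).T)
        self.b = Parameter(np.zeros(4 * d_hidden))
        self._h: Tensor | None = None
        self._c: Tensor | None = None

    def reset_state(self) -> None:
        self._h = self._c = None

    def __call__(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        if self._h is None:
            self._h = Tensor(np.zeros((n, self.d_hidden)))
            self._c = Tensor(np.zeros((n, self.d_hidden)))
        gates = x @ self.wx + self._h @ self.wh + self.b
        H = self.d_hidden
        i = gates[:, 0:H].sigmoid()
        f = gates[:, H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:4 * H].sigmoid()
        self._c = f * self._c + i * g
        self._h = o * self._c.tanh()
        return self._h


class ConvLSTMCell(Module):
    """LSTM with convolutional gates over (N, C, H, W) feature maps."""

    def __init__(self, c_in: int, c_hidden: int, k: int, rng):
        self.c_hidden = c_hidden
        self.wx = Parameter(_glorot(rng, 4 * c_hidden, c_in, k, k))
        self.wh = Parameter(_glorot(rng, 4 * c_hidden, c_hidden, k, k))
        self.b = Parameter(np.zeros(4 * c_hidden))
        self._h: Tensor | None = None
        self._c: Tensor | None = None

    def reset_state(self) -> None:
        self._h = self._c = None

    def __call__(self, x: Tensor) -> Tensor:
        n, _, hh, ww = x.data.shape
        if self._h is None:
            self._h = Tensor(np.zeros((n, self.c_hidden, hh, ww)))
            self._c = Tensor(np.zeros((n, self.c_hidden, hh, ww)))
        gates = conv2d(x, self.wx, self.b) + conv2d(self._h, self.wh)
        C = self.c_hidden
        i = gates[:, 0:C].sigmoid()
        f = gates[:, C:2 * C].sigmoid()
        g = gates[:, 2 * C:3 * C].tanh()
        o = gates[:, 3 * C:4 * C].sigmoid()
        self._c = f * self._c + i * g
        self._h = o * self._c.tanh()
        return self._h


class BiLSTM(Module):
    """Bidirectional LSTM over a full (T, D) sequence -> (T, 2H)."""

    def __init__(self, d_in: int, d_hidden: int, rng):
        self.fwd = LSTMCell(d_in, d_hidden, rng)
        self.bwd = LSTMCell(d_in, d_hidden, rng)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        self.fwd.reset_state()
        self.bwd.reset_state()
        hf = [self.fwd(x) for x in xs]
        hb = list(reversed([self.bwd(x) for x in reversed(xs)]))
        return [concat([a, b], axis=1) for a, b in zip(hf, hb)]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: Tensor, target: np.ndarray,
                  weights: np.ndarray | None = None) -> Tensor:
    """Weighted cross-entropy ``-sum w * t * log p / sum w``."""
    t = np.asarray(target, dtype=float)
    w = np.ones(t.shape[0]) if weights is None else np.asarray(weights, float)
    logp = (probs + 1e-12).log()
    weighted = logp * Tensor(t * w.reshape(-1, *([1] * (t.ndim - 1))))
    return -weighted.sum() * (1.0 / w.sum())
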