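"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train the recurrent classifiers in this package:
dynamic graph, broadcasting-aware elementwise ops, matmul, concat, the
activations the cell equations use, a fused softmax cross-entropy, batch
normalization, and an Adam optimizer.  Gradients flow only into tensors
created with ``requires_grad=True`` (the parameters); inputs enter the
graph as constants.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = parents
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    widths = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + widths)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), bw)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    pos = x.data >= 0
    s = np.empty_like(x.data)
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bw)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    t = np.tanh(x.data)

    def bw(g):
        x._accumulate(g * (1.0 - t * t))

    return _make(t, (x,), bw)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    data = np.maximum(x.data, 0.0)

    def bw(g):
        x._accumulate(g * (x.data > 0))

    return _make(data, (x,), bw)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean negative log-softmax of the true class; fused backward."""
    logits = _as_tensor(logits)
    y = np.asarray(onehot, dtype=float)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.sum(y * (z - np.log(e.sum(axis=1, keepdims=True)))) / n

    def bw(g):
        logits._accumulate(g * (p - y) / n)

    return _make(np.asarray(loss), (logits,), bw)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor,
              eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch normalization over axis 0 of a 2-D tensor.

    Returns the normalized tensor and the batch mean/variance (for the
    caller's running-moment bookkeeping).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=0)
    var = x.data.var(axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    data = gamma.data * xhat + beta.data

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=0))
        beta._accumulate(g.sum(axis=0))
        gd = g * gamma.data
        x._accumulate(inv * (gd - gd.mean(axis=0)
                             - xhat * (gd * xhat).mean(axis=0)))

    return _make(data, (x, gamma, beta), bw), mu, var


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
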