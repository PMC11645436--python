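"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the cross-attention and GIN classifiers
need: broadcast-aware arithmetic, batched matmul, reductions, max with
subgradient routing, concatenation, basic indexing, stable softmax /
log-softmax, layer normalisation and leaky ReLU, plus an Adam optimiser.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph machinery ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=float)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.requires_grad:
            # aliasing the incoming array is safe: gradients are never
            # mutated in place (accumulation always reallocates)
            if self.grad is None:
                grad = np.asarray(grad, dtype=float)
                if grad.shape != self.data.shape:
                    grad = np.broadcast_to(grad, self.data.shape)
                self.grad = grad
            else:
                self.grad = self.grad + grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        return Tensor(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.shape))
        return Tensor(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        return Tensor(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))
        return Tensor(out, (self, other), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor(self.data[idx], (self,), bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))
        return Tensor(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a, b):
        def bw(g):
            self._accum(np.swapaxes(g, a, b))
        return Tensor(np.swapaxes(self.data, a, b), (self,), bw)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Maximum along one axis; gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.max(self.data, axis=axis, keepdims=keepdims)

        def bw(g):
            full = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(full)
        return Tensor(out, (self,), bw)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)
        return Tensor(out, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out)
        return Tensor(out, (self,), bw)

    def abs(self):
        def bw(g):
            self._accum(g * np.sign(self.data))
        return Tensor(np.abs(self.data), (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accum(g * mask)
        return Tensor(self.data * mask, (self,), bw)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=float), requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float))


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    return Tensor(out, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for k, t in enumerate(tensors):
            t._accum(np.take(g, k, axis=axis))
    return Tensor(out, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - as_tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - as_tensor(np.max(x.data, axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    m = x.mean(axis=-1, keepdims=True)
    centred = x - m
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / (var + eps).sqrt() * gain + bias


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, C) logits against integer labels."""
    lp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = lp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class BatchNorm:
    """1-D batch normalisation with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            m = x.mean(axis=0, keepdims=True)
            centred = x - m
            var = (centred * centred).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            return centred / (var + self.eps).sqrt() * self.gamma + self.beta
        centred = x - as_tensor(self.running_mean)
        denom = as_tensor(np.sqrt(self.running_var + self.eps))
        return centred / denom * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]
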