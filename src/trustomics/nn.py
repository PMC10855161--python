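"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the evidential graph-attention model needs:
broadcast-aware arithmetic, batched matmul, reductions, concatenation,
the activations used by the encoder (leaky ReLU, ELU, softplus), masked
softmax, and the special functions (log-gamma, digamma) that appear in the
Dirichlet losses.  Gradients are accumulated by topological-order backward
passes; every primitive is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special as sp_special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents),
                     _prev=parents if any(p.requires_grad for p in parents) else ())
        if out.requires_grad:
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g / b.data, a.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g * a.data / (b.data ** 2), b.shape)

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * exponent * a.data ** (exponent - 1)

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 \
                    else np.expand_dims(g, -1) * b.data
                a.grad += _unbroadcast(ga, a.shape)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 \
                    else np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
                b.grad += _unbroadcast(gb, b.shape)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += np.swapaxes(g, ax1, ax2)

        return self._make(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a.grad += np.broadcast_to(g, a.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a.grad += np.broadcast_to(gg, a.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a.grad += g * od

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g / a.data

        return self._make(np.log(self.data), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * np.where(a.data > 0, 1.0, slope)

        return self._make(np.where(self.data > 0, self.data, slope * self.data),
                          (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g, a=self, nd=neg):
            if a.requires_grad:
                a.grad += g * np.where(a.data > 0, 1.0, nd + alpha)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * sp_special.expit(a.data)

        return self._make(out_data, (self,), backward)

    def gammaln(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * sp_special.digamma(a.data)

        return self._make(sp_special.gammaln(self.data), (self,), backward)

    def digamma(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * sp_special.polygamma(1, a.data)

        return self._make(sp_special.digamma(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        """Softmax along `axis` (max-shifted for stability)."""
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors: list, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _prev=tuple(tensors))
    if out.requires_grad:
        out._backward = backward
    return out


def parameter(rng: np.random.Generator, shape: tuple, fan_in: int,
              fan_out: int) -> Tensor:
    """Glorot-uniform initialized trainable tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of Tensors."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)
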