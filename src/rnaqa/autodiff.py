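"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine carrying exactly the operations the attention
network needs: broadcasting arithmetic, two-operand einsum, reductions,
gather, concatenation, and the usual nonlinearities. Gradients are checked
against central finite differences in the test suite.

All data is float64; operations are deterministic, so a fixed seed gives
bit-identical training traces on one machine.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ---- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autograd core --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad = self.grad + grad

    # ---- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # ---- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        ax = axes if axes else tuple(reversed(range(self.ndim)))
        inv = np.argsort(ax)
        out = Tensor(self.data.transpose(ax), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # ---- reductions & nonlinearities ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / (1.0 + np.exp(-self.data)))
        return out

    # ---- indexing -------------------------------------------------------------
    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum. Every index of each operand must appear in the
    other operand or in the output (true for all contractions used here)."""
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    out = Tensor(np.einsum(subscripts, a.data, b.data), _parents=(a, b))

    def bw(g):
        a._accumulate(np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data))
        b._accumulate(np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (use :func:`einsum` for batched contractions)."""
    return einsum("ij,jk->ik", a, b)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Stable softmax along ``axis``; ``mask`` (boolean, True = keep) excludes
    entries by sending their logits to -inf before normalisation."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    z = x - Tensor(shift)
    if mask is not None:
        z = z + Tensor(np.where(mask, 0.0, -1e30))
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / (var + eps).sqrt() * gain + bias
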