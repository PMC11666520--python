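"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the adversarial imputer and the attention
encoders need: broadcasted arithmetic, (batched) matmul, elementwise
nonlinearities, reductions, reshape/transpose/concat, and numerically
stable softmax / softplus building blocks. Everything runs in float64 and
is deterministic given the caller's random state.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum a broadcasted gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward graph that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Array | None = None
        self._parents: list[tuple["Tensor", Callable[[Array], Array]]] = []

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _result(data: Array, parents: Sequence[tuple["Tensor", Callable]]) -> "Tensor":
        live = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        out = Tensor(data, requires_grad=bool(live))
        out._parents = live
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._result(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ],
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        return Tensor._result(
            self.data**exponent,
            [(self, lambda g: g * exponent * self.data ** (exponent - 1))],
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def grad_a(g: Array) -> Array:
            return _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)

        def grad_b(g: Array) -> Array:
            return _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)

        return Tensor._result(a @ b, [(self, grad_a), (other, grad_b)])

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._result(out_data, [(self, lambda g: g * out_data)])

    def log(self):
        return Tensor._result(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._result(out_data, [(self, lambda g: g * 0.5 / out_data)])

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._result(out_data, [(self, lambda g: g * (1.0 - out_data**2))])

    def relu(self):
        keep = self.data > 0
        return Tensor._result(self.data * keep, [(self, lambda g: g * keep)])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._result(out_data, [(self, lambda g: g * out_data * (1 - out_data))])

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._result(out_data, [(self, lambda g: g * sig)])

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g: Array) -> Array:
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._result(out_data, [(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._result(
            self.data.reshape(shape), [(self, lambda g: g.reshape(old))]
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._result(
            self.data.transpose(axes), [(self, lambda g: g.transpose(inv))]
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._result(
            np.swapaxes(self.data, a, b), [(self, lambda g: np.swapaxes(g, a, b))]
        )

    def __getitem__(self, key):
        def grad_fn(g: Array) -> Array:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return full

        return Tensor._result(self.data[key], [(self, grad_fn)])

    # -- composite helpers ---------------------------------------------------
    def softmax(self, axis: int = -1):
        """Stable softmax along ``axis``; rows sum to one."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1):
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        return (self - shift).exp().sum(axis=axis, keepdims=True).log() + shift

    # -- backward ------------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
        def grad_fn(g: Array, start=start, stop=stop) -> Array:
            slicer = [slice(None)] * g.ndim
            slicer[axis] = slice(start, stop)
            return g[tuple(slicer)]

        parents.append((t, grad_fn))
    return Tensor._result(out_data, parents)


def stack_mean(tensors: Sequence[Tensor]) -> Tensor:
    """Elementwise mean of same-shaped tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out / float(len(tensors))
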