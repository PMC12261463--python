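"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainable pooling operators in this package (attention pooling, BoM
pooling, trainable global pooling) are jointly optimized with small
feed-forward heads.  All of that differentiation is driven by this module:
a :class:`Tensor` wraps a float64 ndarray, records the operations applied
to it, and :meth:`Tensor.backward` accumulates gradients by reverse
topological traversal.

Only the operations the pooling/head computation graphs need are
implemented (broadcasted arithmetic, batched ``matmul``, ``exp``/``tanh``/
``relu``, reductions, reshaping, basic indexing and a numerically stable
``softmax``).  Everything runs in double precision; gradient correctness is
guarded by finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "softmax", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; defaults to d(self)/d(self)=1."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.value.size != 1:
                raise RuntimeError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_val = self.value + other.value

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_val, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.value, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_val = self.value * other.value

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.shape))

        return Tensor(out_val, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_val = self.value / other.value

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.value / other.value**2, other.shape)
                )

        return Tensor(out_val, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_val = self.value**exponent

        def bwd(g):
            self._accumulate(g * exponent * self.value ** (exponent - 1))

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_val = self.value @ other.value

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.value, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.value, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_val, _parents=(self, other), _backward=bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bwd(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.value, a, b), _parents=(self,), _backward=bwd)

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.value.reshape(shape), _parents=(self,), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.value[idx], _parents=(self,), _backward=bwd)

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        out_val = np.exp(self.value)

        def bwd(g):
            self._accumulate(g * out_val)

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.value)

        return Tensor(np.log(self.value), _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        out_val = np.sqrt(self.value)

        def bwd(g):
            self._accumulate(g * 0.5 / out_val)

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        out_val = np.tanh(self.value)

        def bwd(g):
            self._accumulate(g * (1.0 - out_val**2))

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.value > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.value * mask, _parents=(self,), _backward=bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_val = self.value.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_val, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that always requires gradients."""

    def __init__(self, value):
        super().__init__(value, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``.

    The max-subtraction shift is treated as a constant: softmax is invariant
    to constant shifts, so the gradient is unaffected.
    """
    x = as_tensor(x)
    shift = np.max(x.value, axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (backward splits the gradient)."""
    parts = [as_tensor(t) for t in tensors]
    sizes = [p.shape[axis] for p in parts]
    out_val = np.concatenate([p.value for p in parts], axis=axis)
    offsets = np.cumsum([0, *sizes])

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p._accumulate(g[tuple(idx)])

    return Tensor(out_val, _parents=tuple(parts), _backward=bwd)


class Adam:
    """Adam first-order optimizer over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        """Apply one update; ``lr`` overrides the stored rate (schedules)."""
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.value = p.value - lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value
            )
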