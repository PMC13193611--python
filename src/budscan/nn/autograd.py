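"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``. Only the operations needed by the vision/temporal
transformer models in this package are implemented (broadcasted arithmetic,
batched matmul, reductions, reshapes, token gather/concat, exp/log/tanh).

All ops support numpy broadcasting; the backward pass sums gradients over
broadcast dimensions so parameter shapes like ``(1, 1, d)`` work naturally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_tokens", "broadcast_to"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over dimensions that were broadcast up from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        # (..., T, D) @ (D, K): flatten leading dims so BLAS sees one GEMM
        flat = other.data.ndim == 2 and self.data.ndim > 2

        def backward(g):
            if self.requires_grad:
                if flat:
                    g2 = g.reshape(-1, g.shape[-1])
                    ga = (g2 @ other.data.T).reshape(self.data.shape)
                else:
                    ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                      self.data.shape)
                self._accumulate(ga)
            if other.requires_grad:
                if flat:
                    a2 = self.data.reshape(-1, self.data.shape[-1])
                    g2 = g.reshape(-1, g.shape[-1])
                    other._accumulate(a2.T @ g2)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.data.shape))

        if flat:
            a2 = self.data.reshape(-1, self.data.shape[-1])
            out = (a2 @ other.data).reshape(*self.data.shape[:-1], other.data.shape[-1])
        else:
            out = self.data @ other.data
        return self._make(out, (self, other), backward)

    # -- elementwise transcendentals -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), backward)

    # -- reductions & shape ops ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, key, g)
                self._accumulate(gx)

        return self._make(self.data[key], (self,), backward)

    # -- graph traversal --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        # Reverse topological order guarantees every node's output gradient is
        # fully accumulated before its own backward rule fires.
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)
            node.grad = None  # free intermediate grads to bound memory


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select tokens along axis 1: ``out[b, k] = x[b, idx[b, k]]``.

    ``x`` has shape (B, T, D) and ``idx`` integer shape (B, K).
    """
    idx = np.asarray(idx)
    b_idx = np.arange(x.data.shape[0])[:, None]
    out_data = x.data[b_idx, idx]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (b_idx, idx), g)
            x._accumulate(gx)

    return x._make(out_data, (x,), backward)


def broadcast_to(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g, x.data.shape))

    return x._make(np.broadcast_to(x.data, shape), (x,), backward)
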