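"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray and records the operations
applied to it.  Calling :meth:`Tensor.backward` on a scalar result walks the
recorded graph in reverse topological order and accumulates gradients into
every tensor with ``requires_grad=True`` (gradients are kept on intermediate
tensors as well, which is what the Grad-CAM machinery relies on).

Only the primitives the classifier needs are implemented; everything higher
level (layer norm, softmax, batch norm, attention) is composed from these in
:mod:`histofusion.nn.layers`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph recording (used in eval loops)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)

        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (50-layer nets)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                pgrad = _unbroadcast(pgrad, parent.data.shape)
                parent.grad = pgrad if parent.grad is None else parent.grad + pgrad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return ((self, g), (other, g))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return ((self, g * other.data), (other, g * self.data))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return ((self, g / other.data),
                    (other, -g * self.data / (other.data ** 2)))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else \
                    g[..., None] * b
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else a * g
            else:
                gb = np.swapaxes(a, -1, -2) @ g
            return ((self, ga), (other, gb))

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return ((self, g / self.data),)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out_data = out_data.astype(np.float32)

        def backward(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU; its derivative is taken analytically.
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dt = (1.0 - t ** 2) * dinner
            return ((self, g * (0.5 * (1.0 + t) + 0.5 * x * dt)),)

        return Tensor._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.data.shape).copy()),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g):
            return ((self, g.reshape(old_shape)),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Select ``out[i] = self[i, index[i]]`` (per-row gather)."""
        rows = np.arange(self.data.shape[0])
        out_data = self.data[rows, index]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, index), g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, pieces))

    return Tensor._make(out_data, tuple(tensors), backward)
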