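"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a graph-convolutional classifier: matmul,
broadcast add/mul, relu/tanh/sigmoid, axis reductions (sum/mean/max),
row selection, concatenation and a numerically stable binary
cross-entropy.  Gradients are accumulated by topological-order backward
passes; everything is float64 and single-threaded, so runs are
bit-reproducible.  Checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- ops -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def matmul(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sigmoid(self) -> "Tensor":
        out_data = _sigmoid(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        """Reduction max; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis).squeeze(axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return Tensor(out_data, parents=(self,), backward=backward)

    def rows(self, index) -> "Tensor":
        """Select rows (axis 0) by an integer index array."""
        index = np.asarray(index, dtype=int)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accum(full)

        return Tensor(self.data[index], parents=(self,), backward=backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    # -- autodiff driver -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits (stable log-sum-exp form).

    loss = mean( max(z,0) − z·y + log(1 + exp(−|z|)) )
    """
    z = logits.data
    y = np.asarray(targets, dtype=float)
    out_data = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))

    def backward(g):
        logits._accum(g * (_sigmoid(z) - y) / z.size)

    return Tensor(out_data, parents=(logits,), backward=backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g
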