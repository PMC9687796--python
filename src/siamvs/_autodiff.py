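"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the Siamese scorers: dense
and 1-D convolution layers, ReLU/sigmoid, elementwise arithmetic,
absolute value, exponential, reductions, max-pooling and elementwise
maximum.  Tensors record their parents and a backward closure; calling
:meth:`Tensor.backward` walks the tape in reverse topological order.

Gradients are accumulated (summed) into ``.grad`` with broadcasting
handled by summing reduced axes back to the parent's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "RMSProp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to produce it."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ---------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return Tensor._node(self.data - other.data, (self, other), backward)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        return Tensor._node(np.abs(self.data), (self,), lambda g: (g * sign,))

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._node(
            out_data, (self,), lambda g: (g * out_data * (1 - out_data),)
        )

    def log(self) -> "Tensor":
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._node(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            return (np.broadcast_to(g / n, self.shape).copy(),)

        return Tensor._node(self.data.mean(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        def backward(g):
            return (g.reshape(self.shape),)

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    # -- binary elementwise max -------------------------------------------

    def maximum(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        take_self = self.data >= other.data  # ties route to first argument

        def backward(g):
            return (
                _unbroadcast(g * take_self, self.shape),
                _unbroadcast(g * ~take_self, other.shape),
            )

        return Tensor._node(
            np.maximum(self.data, other.data), (self, other), backward
        )

    # -- structured layers --------------------------------------------------

    def conv1d_same(self, kernel: "Tensor") -> "Tensor":
        """1-D convolution, 'same' zero padding.

        ``self``: (B, L, C_in); ``kernel``: (K, C_in, C_out) with odd K.
        Implemented as im2col + matmul.
        """
        B, L, Cin = self.shape
        K, KCin, Cout = kernel.shape
        if KCin != Cin:
            raise ValueError("kernel channel mismatch")
        if K % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        pad = K // 2
        xp = np.zeros((B, L + 2 * pad, Cin))
        xp[:, pad : pad + L, :] = self.data
        # cols: (B, L, K*Cin)
        cols = np.stack([xp[:, k : k + L, :] for k in range(K)], axis=2)
        cols = cols.reshape(B, L, K * Cin)
        Wk = kernel.data.reshape(K * Cin, Cout)
        out_data = cols @ Wk

        def backward(g):
            # g: (B, L, Cout)
            gW = np.tensordot(cols, g, axes=([0, 1], [0, 1]))  # (K*Cin, Cout)
            gcols = g @ Wk.T  # (B, L, K*Cin)
            gcols = gcols.reshape(B, L, K, Cin)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + L, :] += gcols[:, :, k, :]
            return (gxp[:, pad : pad + L, :], gW.reshape(K, Cin, Cout))

        return Tensor._node(out_data, (self, kernel), backward)

    def maxpool1d(self, size: int = 2) -> "Tensor":
        """Non-overlapping 1-D max pooling over axis 1 of (B, L, C)."""
        B, L, C = self.shape
        if L % size != 0:
            raise ValueError(f"length {L} not divisible by pool size {size}")
        x = self.data.reshape(B, L // size, size, C)
        out_data = x.max(axis=2)
        # route gradient to the first maximal element of each window
        expanded = out_data[:, :, None, :]
        is_max = x == expanded
        first = np.cumsum(is_max, axis=2) == 1
        mask = is_max & first

        def backward(g):
            gx = mask * g[:, :, None, :]
            return (gx.reshape(B, L, C),)

        return Tensor._node(out_data, (self,), backward)

    # -- backward pass ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() starts from a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


class RMSProp:
    """RMSprop with the usual leaky squared-gradient accumulator."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.rho = float(rho)
        self.eps = float(eps)
        self._cache = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, c in zip(self.params, self._cache):
            if p.grad is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
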