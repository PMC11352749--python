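"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core behind the package's neural components (the
conditional GAN, the denoising autoencoder and the attention classifier).
It implements exactly the primitives those models need: broadcasting
arithmetic, matrix products, the usual activations, reductions, reshape /
concatenate / row-gather, and a numerically stable softplus for
cross-entropy-on-logit losses.

Gradients flow through a dynamically built tape; broadcasting is undone by
summing gradient contributions over the broadcast axes. Correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes of size 1 that were stretched
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------

    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                return (g @ b.T, a.T @ g)
            if b.ndim == 2:
                # batched input x 2-D weight: collapse batch axes instead of
                # materializing per-sample outer products
                ga = g @ b.T
                gb = (a.reshape(-1, a.shape[-1]).T
                      @ g.reshape(-1, g.shape[-1]))
                return (ga, gb)
            # general batched case (..., m, k) @ (..., k, n)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._op(out_data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._op(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.1):
        mult = np.where(self.data > 0, 1.0, slope)
        return Tensor._op(self.data * mult, (self,), lambda g: (g * mult,))

    def softplus(self):
        """log(1 + exp(x)), computed stably for large |x|."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._op(out_data, (self,), lambda g: (g * sig,))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._op(out_data, (self,), backward)

    # -- reductions & shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor._op(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    def take_rows(self, idx: np.ndarray):
        """Row gather, the forward pass of an embedding lookup."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return (acc,)

        return Tensor._op(out_data, (self,), backward)

    # -- backward pass ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            elif node.requires_grad:  # leaf
                node.grad = g if node.grad is None else node.grad + g
        # leaves reached directly inside the loop above were handled; the
        # root itself may be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(out_data, tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return a @ b
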