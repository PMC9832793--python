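"""Compact reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the survival networks in this package: tensors
carrying a gradient, broadcast-aware elementwise ops, (batched) matrix
multiplication, reductions, SELU, softmax building blocks, concatenation
and an Adam optimizer.  Backpropagation runs over a topological sort of
the recorded graph.  Gradients are exact (verified against central finite
differences in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "selu", "softmax_lastaxis", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev if self.requires_grad else ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g)  # private copy; avoids a zero-fill pass
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- elementwise ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):   # scalar fast path, dtype-preserving
            out = Tensor(self.data + other, _prev=(self,))

            def back_s():
                if self.requires_grad:
                    self._accum(out.grad)

            out._backward = back_s
            return out
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):   # scalar fast path, dtype-preserving
            out = Tensor(self.data * other, _prev=(self,))

            def back_s():
                if self.requires_grad:
                    self._accum(out.grad * other)

            out._backward = back_s
            return out
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(np.power(self.data, exponent), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad * exponent * np.power(self.data, exponent - 1.0))

        out._backward = back
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = back
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = back
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- linear algebra -------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def back():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = back
        return out

    __matmul__ = matmul

    # -- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def back():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = back
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(np.transpose(self.data, axes), _prev=(self,))
        inv = np.argsort(axes)

        def back():
            if self.requires_grad:
                self._accum(np.transpose(out.grad, inv))

        out._backward = back
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                     _prev=tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(g)

        out._backward = back
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- nonlinearities -----------------------------------------------------

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def selu(x: Tensor) -> Tensor:
    """Scaled exponential linear unit (self-normalizing activation)."""
    pos = x.data > 0
    out = Tensor(
        _SELU_SCALE * np.where(pos, x.data, _SELU_ALPHA * np.expm1(x.data)),
        _prev=(x,),
    )

    def back():
        if x.requires_grad:
            local = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * np.exp(x.data))
            x._accum(out.grad * local)

    out._backward = back
    return out


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis (fused node)."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def back():
        if x.requires_grad:
            g = out.grad
            dot = (g * s).sum(axis=-1, keepdims=True)
            x._accum(s * (g - dot))

    out._backward = back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned scale/shift (fused)."""
    d = x.data.shape[-1]
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _prev=(x, gamma, beta))

    def back():
        g = out.grad
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx.sum(axis=-1, keepdims=True)
            t2 = (gx * xhat).sum(axis=-1, keepdims=True)
            x._accum(inv * (gx - t1 / d - xhat * t2 / d))

    out._backward = back
    return out


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
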