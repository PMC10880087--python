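"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the atom-bond transformer needs: broadcasting
elementwise arithmetic, matrix products, ReLU, exp, reductions, concatenation
and transposition.  Gradients are float64 throughout; graphs are built per
forward pass and freed afterwards.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "exp", "softmax_rows", "layer_norm",
           "Adam", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _attach(out: "Tensor", backward) -> "Tensor":
    # closures capture their output tensor; attach only when the graph is
    # live so inference builds no reference cycles
    if out.requires_grad:
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that broadcasting expanded to reach `shape`."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = _grad_enabled and (
            requires_grad or any(p.requires_grad for p in parents))
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this node; `grad` defaults to ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the graph eagerly: drop intermediate grads and break the
        # closure/parent reference cycles so large arrays free immediately
        for node in topo:
            if node._parents:
                node._parents = ()
                node._backward = None
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return _attach(out, backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return _attach(out, backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * exponent * self.data ** (exponent - 1.0), self.shape))

        return _attach(out, backward)

    def __matmul__(self, other):
        """Matrix product; supports batched stacks per np.matmul semantics
        (operands must be >= 2-D; gradients of broadcast operands are summed
        over the broadcast axes)."""
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return _attach(out, backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float64))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).astype(np.float64))

        return _attach(out, backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return _attach(out, backward)

    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return _attach(out, backward)

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inverse = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inverse))

        return _attach(out, backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _attach(out, backward)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0.0))

    return _attach(out, backward)


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * out.data)

    return _attach(out, backward)


def softmax_rows(logits: Tensor) -> Tensor:
    """Row-wise softmax of a 2-D tensor (stable: row max treated as constant)."""
    shifted = logits + Tensor(-logits.data.max(axis=-1, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = centered.pow(2.0).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gain + bias


class Adam:
    """Adaptive-moment-estimation optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * p.grad
            v = self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
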