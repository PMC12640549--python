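"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains its networks full-batch on CPU, so the engine only
implements the operations the model graph needs: broadcasting arithmetic,
(batched) matrix products, ELU/sigmoid/softmax, reductions, reshaping, row
gather/scatter for edge-wise message passing, and value clipping. Gradients
are accumulated by topological sort from the loss node.

All tensors carry plain ``numpy.ndarray`` data; dtype is whatever the caller
supplies and is preserved through every operation.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- autograd driver ------------------------------------------------------
    def backward(self, free_graph: bool = True) -> None:
        """Backpropagate from this (scalar) tensor.

        With ``free_graph`` (the default) intermediate activations, their
        gradients, and the closure references forming the graph are released
        as soon as each node has been processed; only leaf tensors (e.g.
        :class:`Parameter`) keep their gradients. This breaks the reference
        cycles the backward closures create and keeps peak memory at roughly
        the forward-pass footprint.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if free_graph and node._parents:
                node.grad = None
                node._parents = ()
                node._backward = None

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x, like: np.ndarray | None = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # keep python scalars from upcasting float32 graphs to float64
        if like is not None and np.isscalar(x):
            return Tensor(np.asarray(x, dtype=like.dtype))
        return Tensor(np.asarray(x))

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = Tensor._lift(other, like=self.data)
        out = Tensor(fwd(self.data, other.data))
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._parents = (self, other)

            def _backward(a=self, b=other, out=out):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(bwd_a(out.grad, a.data, b.data), a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(bwd_b(out.grad, a.data, b.data), b.data.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other, like=self.data).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e)
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)

            def _backward(a=self, out=out):
                a._accumulate(out.grad * e * a.data ** (e - 1.0))

            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data)
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._parents = (self, other)

            def _backward(a=self, b=other, out=out):
                g = out.grad
                if a.requires_grad:
                    if b.data.ndim == 1:
                        ga = np.outer(g, b.data) if a.data.ndim == 2 else g * b.data
                    else:
                        ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accumulate(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    if a.data.ndim == 1:
                        gb = np.outer(a.data, g)
                    else:
                        gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accumulate(_unbroadcast(gb, b.data.shape))

            out._backward = _backward
        return out

    # -- unary ops ------------------------------------------------------------
    def _unary(self, fwd_val: np.ndarray, grad_fn) -> "Tensor":
        out = Tensor(fwd_val)
        out.requires_grad = self.requires_grad
        if out.requires_grad:
            out._parents = (self,)

            def _backward(a=self, out=out):
                a._accumulate(grad_fn(out.grad, a.data, out.data))

            out._backward = _backward
        return out

    def exp(self):
        return self._unary(np.exp(self.data), lambda g, a, o: g * o)

    def log(self):
        return self._unary(np.log(self.data), lambda g, a, o: g / a)

    def sigmoid(self):
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.maximum(x, 0))),
                       np.exp(np.minimum(x, 0)) / (1.0 + np.exp(np.minimum(x, 0))))
        return self._unary(val, lambda g, a, o: g * o * (1.0 - o))

    def elu(self, alpha: float = 1.0):
        val = np.where(self.data > 0, self.data,
                       alpha * np.expm1(np.minimum(self.data, 0)))
        return self._unary(val, lambda g, a, o: g * np.where(a > 0, 1.0, o + alpha))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the interval."""
        val = np.clip(self.data, lo, hi)
        return self._unary(val, lambda g, a, o: g * ((a >= lo) & (a <= hi)))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g, a, o, axis=axis):
            dot = (g * o).sum(axis=axis, keepdims=True)
            return o * (g - dot)

        return self._unary(val, grad_fn)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        val = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, a, o, axis=axis, keepdims=keepdims):
            if axis is None:
                return np.broadcast_to(g, a.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, a.shape).copy()

        return self._unary(val, grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return self._unary(self.data.reshape(shape),
                           lambda g, a, o, orig=orig: g.reshape(orig))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = tuple(np.argsort(axes))
        return self._unary(self.data.transpose(axes),
                           lambda g, a, o, inv=inv: g.transpose(inv))

    @property
    def T(self):
        return self.transpose()

    def gather_rows(self, idx: np.ndarray):
        """Select rows ``self[idx]`` (idx may repeat)."""
        idx = np.asarray(idx, dtype=np.intp)

        def grad_fn(g, a, o, idx=idx):
            ga = np.zeros_like(a)
            np.add.at(ga, idx, g)
            return ga

        return self._unary(self.data[idx], grad_fn)

    def scatter_add_rows(self, idx: np.ndarray, n: int):
        """Return an ``(n, ...)`` tensor with ``self``'s rows summed into ``idx``."""
        idx = np.asarray(idx, dtype=np.intp)
        val = np.zeros((n,) + self.data.shape[1:], dtype=self.data.dtype)
        np.add.at(val, idx, self.data)
        return self._unary(val, lambda g, a, o, idx=idx: g[idx])


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.array(data), requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: Sequence[float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
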