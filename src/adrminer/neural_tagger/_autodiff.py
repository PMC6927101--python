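"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the tagger: broadcast-aware elementwise ops,
matmul, slicing/gather, concatenation, max-pooling and log-sum-exp, with
gradients accumulated through a topologically sorted tape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node on the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                elif a.ndim == 1:
                    self._accum(g @ b.T)
                elif b.ndim == 1:
                    self._accum(np.outer(g, b))
                else:
                    self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._accum(g * a)
                elif a.ndim == 1:
                    other._accum(np.outer(a, g))
                elif b.ndim == 1:
                    other._accum(a.T @ g)
                else:
                    other._accum(a.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    # -- reductions & reshaping -------------------------------------------

    def sum(self, axis=None) -> "Tensor":
        out_data = self.data.sum(axis=axis)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self) -> "Tensor":
        return self.sum() / self.data.size

    def max(self, axis: int) -> "Tensor":
        out_data = self.data.max(axis=axis)
        mask = self.data == np.expand_dims(out_data, axis)
        # split ties evenly so the gradient check stays exact
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            self._accum(np.expand_dims(g, axis) * mask)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def logsumexp(self, axis: int) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        ex = np.exp(self.data - m)
        s = ex.sum(axis=axis)
        out_data = np.squeeze(m, axis=axis) + np.log(s)
        softmax = ex / np.expand_dims(s, axis)

        def bwd(g):
            self._accum(np.expand_dims(g, axis) * softmax)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def bwd(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            self._accum(buf)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def stack_rows(rows: Iterable[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor along a new first axis."""
    return concat([r.reshape(1, -1) for r in rows], axis=0)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


class Nadam:
    """Nesterov-accelerated adaptive moment estimation (NADAM).

    Implements the Dozat update: Adam's bias-corrected moments with a
    Nesterov look-ahead on the first moment.
    """

    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 2e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        grad_norm_clip: float | None = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.grad_norm_clip = grad_norm_clip
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        grads = {
            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
            for k, p in self.params.items()
        }
        if self.grad_norm_clip is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.grad_norm_clip:
                scale = self.grad_norm_clip / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g**2
            m_hat = self._m[k] / (1 - b1 ** (self.t + 1))
            v_hat = self._v[k] / (1 - b2**self.t)
            m_nesterov = b1 * m_hat + (1 - b1) * g / (1 - b1**self.t)
            p.data -= self.lr * m_nesterov / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
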