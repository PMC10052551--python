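"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the graph layers need: dense matmul,
broadcast add/mul/div, row gather/scatter (the sparse message-passing
primitives), column concatenation, elementwise nonlinearities, exp/log and
reductions. Gradients are accumulated by topological-order backpropagation.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # copy on first write: g may alias a consumer's grad buffer
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.requires_grad:
                node._backward()

    # convenience operators ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, scale(other, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.data, b.shape))

    out._backward = backward
    return out


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-out.grad * a.data / (b.data**2), b.shape))

    out._backward = backward
    return out


def scale(a, c: float) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data * c, parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * c)

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ out.grad)

    out._backward = backward
    return out


def gather_rows(a, idx: np.ndarray) -> Tensor:
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.data[idx], parents=(a,))

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._accumulate(g)

    out._backward = backward
    return out


def scatter_add_rows(a, idx: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``a`` into ``n`` output rows by index (segment sum)."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    data = np.zeros((n,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(data, idx, a.data)
    out = Tensor(data, parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad[idx])

    out._backward = backward
    return out


def spmm(S, ST, a) -> Tensor:
    """Constant sparse matrix times dense tensor; ST is the transpose of S.

    The fast path for graph message passing (row gather, neighbor sums and
    mean aggregation are all sparse matrices applied to the feature matrix).
    """
    a = _as_tensor(a)
    out = Tensor(S @ a.data, parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(ST @ out.grad)

    out._backward = backward
    return out


def concat_cols(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))
    na = a.data.shape[1]

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad[:, :na])
        if b.requires_grad:
            b._accumulate(out.grad[:, na:])

    out._backward = backward
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * (a.data > 0))

    out._backward = backward
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * np.where(a.data > 0, 1.0, slope))

    out._backward = backward
    return out


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out = Tensor(np.where(a.data > 0, a.data, neg), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * np.where(a.data > 0, 1.0, neg + alpha))

    out._backward = backward
    return out


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * out.data)

    out._backward = backward
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad / a.data)

    out._backward = backward
    return out


def rowsum(a) -> Tensor:
    """Sum over axis 1, keepdims."""
    a = _as_tensor(a)
    out = Tensor(a.data.sum(axis=1, keepdims=True), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(np.broadcast_to(out.grad, a.shape).copy())

    out._backward = backward
    return out


def total(a) -> Tensor:
    """Sum of all entries (scalar)."""
    a = _as_tensor(a)
    out = Tensor(a.data.sum(), parents=(a,))

    def backward():
        if a.requires_grad:
            a._accumulate(np.full(a.shape, out.grad))

    out._backward = backward
    return out


def segment_softmax(e: Tensor, seg: np.ndarray, n: int) -> Tensor:
    """Softmax of edge values ``e`` (E x 1) within segments given by ``seg``.

    The per-segment max is detached (softmax is shift-invariant), the
    standard numerically stable formulation.
    """
    seg = np.asarray(seg, dtype=np.intp)
    m = np.full((n, 1), -np.inf)
    np.maximum.at(m, seg, e.data)
    z = exp(add(e, Tensor(-m[seg])))
    denom = scatter_add_rows(z, seg, n)
    return div(z, gather_rows(denom, seg))
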