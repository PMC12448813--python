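"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just the operations the association model needs: broadcasting arithmetic,
(batched) matmul, row gathers with scatter-add backward, reshapes and
concatenation, elementwise exp/log/sigmoid/softplus, masked softmax and a
masked log-sum-exp, axis sums — plus an Adam optimiser.  Gradients are
accumulated by topological traversal from a scalar loss.

Not a general-purpose library: shapes are assumed consistent, and only the
differentiability the model exercises is implemented (and unit-tested
against finite differences).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "sparse_matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _scatter_rows(n_rows: int, idx: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Segment-sum ``g`` rows by ``idx`` into an (n_rows, d) array.

    Implemented as a one-hot sparse matmul, which is far faster than
    ``np.add.at`` at the gather sizes the model produces.
    """
    from scipy import sparse

    idx = idx.ravel()
    g2 = g.reshape(len(idx), -1)
    onehot = sparse.csr_matrix(
        (np.ones(len(idx), dtype=g.dtype), idx, np.arange(len(idx) + 1)),
        shape=(len(idx), n_rows),
    )
    return onehot.T @ g2


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad", "_grad_owned")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool | None = None,
    ):
        self.value = np.asarray(value)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self._grad_owned = False
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad

    # -- graph bookkeeping --------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is stored by reference (possibly a broadcast
        # view); only a second contribution materialises an owned buffer
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
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
        self.grad = np.ones_like(self.value)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x), requires_grad=False)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.value / (other.value**2), other.value.shape)
                )

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))
        a, b = self.value, other.value

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.value.shape
        out = Tensor(self.value.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.value, a, b), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(np.swapaxes(g, a, b))
        return out

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Row lookup ``self[idx]`` (idx any integer array); scatter-add grad."""
        idx = np.asarray(idx)
        out = Tensor(self.value[idx], (self,))

        def bwd(g):
            if self.requires_grad:
                acc = _scatter_rows(self.value.shape[0], idx, np.ascontiguousarray(g))
                self._accumulate(acc.reshape(self.value.shape).astype(self.value.dtype, copy=False))

        out._backward = bwd
        return out

    def index(self, key) -> "Tensor":
        """Basic (slice/int-tuple) indexing with scatter backward."""
        out = Tensor(self.value[key], (self,))

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.value)
                np.add.at(acc, key, g)
                self._accumulate(acc)

        out._backward = bwd
        return out

    @staticmethod
    def concat(parts: Sequence["Tensor"], axis: int = -1) -> "Tensor":
        parts = [Tensor._lift(p) for p in parts]
        out = Tensor(np.concatenate([p.value for p in parts], axis=axis), tuple(parts))
        sizes = [p.value.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for p, piece in zip(parts, np.split(g, splits, axis=axis)):
                if p.requires_grad:
                    p._accumulate(piece)

        out._backward = bwd
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.value.shape

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise --------------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.value)
        out = Tensor(val, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.value)
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-np.clip(self.value, -60, 60)))
        out = Tensor(val, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val * (1 - val))
        return out

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), numerically stable."""
        x = self.value
        val = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(val, (self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * sig)
        return out

    def masked_softmax(self, mask: np.ndarray, axis: int = -1) -> "Tensor":
        """Softmax along ``axis`` over positions where ``mask`` is True.

        Masked positions get weight 0; a fully-masked slice yields an
        all-zero row (the model's convention for empty layers).
        """
        x = np.where(mask, self.value, -np.inf)
        shift = np.max(x, axis=axis, keepdims=True)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        e = np.exp(x - shift)
        denom = e.sum(axis=axis, keepdims=True)
        val = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                inner = (g * val).sum(axis=axis, keepdims=True)
                self._accumulate(val * (g - inner))

        out._backward = bwd
        return out

    def masked_logsumexp(self, mask: np.ndarray, axis: int = -1) -> "Tensor":
        """log Σ_masked exp(x) along ``axis``; grad is the masked softmax."""
        x = np.where(mask, self.value, -np.inf)
        shift = np.max(x, axis=axis, keepdims=True)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        e = np.exp(x - shift)
        s = e.sum(axis=axis, keepdims=True)
        val = (np.log(np.maximum(s, 1e-300)) + shift).squeeze(axis)
        soft = np.divide(e, s, out=np.zeros_like(e), where=s > 0)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.expand_dims(g, axis) * soft)

        out._backward = bwd
        return out


def sparse_matmul(w, x: Tensor) -> Tensor:
    """``w @ x`` for a constant scipy sparse ``w``; grad flows into ``x``."""
    out = Tensor(np.asarray(w @ x.value), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.asarray(w.T @ g))

    out._backward = bwd
    return out


class Parameter(Tensor):
    """Leaf tensor updated by the optimiser."""

    def __init__(self, value: np.ndarray):
        super().__init__(np.array(value), requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
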