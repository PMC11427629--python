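"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This is the tensor substrate for the graph networks in :mod:`surfbind.nn`.
It implements exactly the primitives those networks need — elementwise
arithmetic with broadcasting, matrix products, gathers/concats, sigmoid and
softplus nonlinearities, per-segment reductions (sum/mean/min/max) over graph
edges, and sparse interpolation — each with a hand-written vector-Jacobian
product.  Gradients are accumulated lazily in a topological-order backward
sweep; scatter-adds over edge indices go through precomputed
:class:`ScatterIndex` sort/``reduceat`` plans, which is what keeps training
tractable on a CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sparse

__all__ = ["Tensor", "ScatterIndex", "concat", "gather", "segment_sum",
           "segment_mean", "segment_min", "segment_max", "interp", "sigmoid",
           "softplus", "relu", "log", "exp", "sqrt"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_vjp", "requires_grad",
                 "_grad_owned")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._vjp = vjp
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        """Lazily accumulate a gradient contribution (no pre-zeroing)."""
        if self.grad is None:
            self.grad = g          # may alias the producer's buffer
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = {id(self)}
        stack: list[tuple[Tensor, any]] = [(self, iter(self._parents))]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        for t in topo:
            t.grad = None
            t._grad_owned = False
        self.grad = np.asarray(grad, dtype=float).reshape(self.data.shape)
        for t in reversed(topo):
            if t._vjp is not None and t.grad is not None:
                t._vjp(t.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g, other.data.shape))

        out._vjp = vjp
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(-g)

        out._vjp = vjp
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._vjp = vjp
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape
                ))

        out._vjp = vjp
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(g @ other.data.T)
            if other.requires_grad:
                other.accumulate(self.data.T @ g)

        out._vjp = vjp
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def vjp(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.accumulate(np.broadcast_to(gg, self.data.shape))

        out._vjp = vjp
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def vjp(g):
            if self.requires_grad:
                self.accumulate(g.reshape(self.data.shape))

        out._vjp = vjp
        return out

    def slice_cols(self, j0: int, j1: int):
        out = Tensor(self.data[:, j0:j1], (self,))

        def vjp(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, j0:j1] = g
                self.accumulate(full)

        out._vjp = vjp
        return out

    def slice_rows(self, i0: int, i1: int):
        out = Tensor(self.data[i0:i1], (self,))

        def vjp(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[i0:i1] = g
                self.accumulate(full)

        out._vjp = vjp
        return out


# ---------------------------------------------------------------------------
# scatter plans


class ScatterIndex:
    """A precomputed plan for scatter-adding edge rows into node rows.

    Sorting the edge index once and using ``ufunc.reduceat`` afterwards is
    far cheaper than repeated ``np.add.at`` calls; the same plan also
    provides segment min/max with tie-splitting gradients.
    """

    def __init__(self, idx: np.ndarray, n: int):
        self.idx = np.asarray(idx, dtype=int)
        self.n = int(n)
        self.order = np.argsort(self.idx, kind="stable")
        self.sorted_idx = self.idx[self.order]
        self.unique, self.starts = np.unique(self.sorted_idx, return_index=True)
        self.counts = np.bincount(self.idx, minlength=self.n).astype(float)
        self.is_identity_order = bool(np.all(self.order == np.arange(len(self.idx))))

    def scatter_add(self, arr: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n,) + arr.shape[1:], dtype=float)
        if len(self.idx) == 0:
            return out
        a = arr if self.is_identity_order else arr[self.order]
        out[self.unique] = np.add.reduceat(a, self.starts, axis=0)
        return out

    def scatter_extreme(self, arr: np.ndarray, ufunc) -> np.ndarray:
        fill = 0.0
        out = np.zeros((self.n,) + arr.shape[1:], dtype=float)
        if len(self.idx) == 0:
            return out
        a = arr if self.is_identity_order else arr[self.order]
        out[self.unique] = ufunc.reduceat(a, self.starts, axis=0)
        return out


def gather(x: Tensor, idx: np.ndarray,
           scatter: ScatterIndex | None = None) -> Tensor:
    """Row gather ``x[idx]``; the gradient scatter-adds back (using the
    precomputed plan when given)."""
    out = Tensor(x.data[idx], (x,))

    def vjp(g):
        if not x.requires_grad:
            return
        if scatter is not None:
            x.accumulate(scatter.scatter_add(g))
        else:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x.accumulate(acc)

    out._vjp = vjp
    return out


def segment_sum(x: Tensor, scatter: ScatterIndex) -> Tensor:
    """Sum rows of ``x`` into segments; empty segments are 0."""
    out = Tensor(scatter.scatter_add(x.data), (x,))

    def vjp(g):
        if x.requires_grad:
            x.accumulate(g[scatter.idx])

    out._vjp = vjp
    return out


def segment_mean(x: Tensor, scatter: ScatterIndex) -> Tensor:
    counts = np.maximum(scatter.counts, 1.0)
    inv = (1.0 / counts)[:, None] if x.data.ndim > 1 else 1.0 / counts
    return segment_sum(x, scatter) * Tensor(inv)


def _segment_extreme(x: Tensor, scatter: ScatterIndex, ufunc) -> Tensor:
    val = scatter.scatter_extreme(x.data, ufunc)
    out = Tensor(val, (x,))
    # gradient flows to the rows attaining the extreme (split over ties)
    ties = (x.data == val[scatter.idx]).astype(float)
    denom = np.maximum(scatter.scatter_add(ties), 1.0)

    def vjp(g):
        if x.requires_grad:
            x.accumulate(ties * (g / denom)[scatter.idx])

    out._vjp = vjp
    return out


def segment_min(x: Tensor, scatter: ScatterIndex) -> Tensor:
    return _segment_extreme(x, scatter, np.minimum)


def segment_max(x: Tensor, scatter: ScatterIndex) -> Tensor:
    return _segment_extreme(x, scatter, np.maximum)


# ---------------------------------------------------------------------------
# functional primitives


def _unary(x: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = Tensor(value, (x,))

    def vjp(g):
        if x.requires_grad:
            x.accumulate(g * local_grad)

    out._vjp = vjp
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return _unary(x, s, s * (1.0 - s))


def softplus(x: Tensor) -> Tensor:
    v = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return _unary(x, v, s)


def relu(x: Tensor) -> Tensor:
    return _unary(x, np.maximum(x.data, 0.0), (x.data > 0).astype(float))


def exp(x: Tensor) -> Tensor:
    v = np.exp(np.clip(x.data, -700, 700))
    return _unary(x, v, v)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    v = np.sqrt(x.data)
    return _unary(x, v, 0.5 / np.maximum(v, 1e-12))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.accumulate(g[tuple(sl)])

    out._vjp = vjp
    return out


def interp(S: _sparse.spmatrix, x: Tensor) -> Tensor:
    """Sparse linear map ``S @ x`` (e.g. KNN interpolation weights)."""
    out = Tensor(S @ x.data, (x,))
    St = S.T.tocsr()

    def vjp(g):
        if x.requires_grad:
            x.accumulate(St @ g)

    out._vjp = vjp
    return out
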