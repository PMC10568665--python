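"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is a small tensor autodiff engine: a :class:`Tensor` wraps an
``ndarray`` and records the operations applied to it; :meth:`Tensor.backward`
walks the recorded graph in reverse topological order and accumulates
gradients. Only the operations needed by the graph-attention encoder, the
capsule head and the training loop are provided, including segment
(per-neighbourhood / per-graph) reductions for batched molecular graphs.

Gradients of broadcast operations are reduced back to the operand shape with
:func:`_unbroadcast`. Dropout and other stochastic masks are applied as
constant multipliers so they participate in the graph without being
differentiated themselves.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "gather", "segment_sum",
           "segment_softmax", "segment_max", "dropout_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes of size 1 that were expanded
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # stored by reference on first accumulation; all writers produce
        # fresh arrays and accumulation itself never mutates in place
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.asarray(grad)
        else:
            self.grad = self.grad + grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            if self.data.ndim >= 2:
                ga = _unbroadcast(ga, self.shape)
            if other.data.ndim >= 2:
                gb = _unbroadcast(gb, other.shape)
            self._accum(ga)
            other._accum(gb)
        out._backward = back
        return out

    # -- elementwise -------------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        pos = self.data > 0
        fac = np.where(pos, 1.0, slope)
        out = Tensor(self.data * fac, parents=(self,))
        out._backward = lambda g: self._accum(g * fac)
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        val = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, val + alpha))
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accum(
            g.transpose(*inv) if inv is not None else g.transpose())
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))
        out._backward = back
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = back
        return out


class Parameter(Tensor):
    """A trainable tensor (leaf of the autodiff graph)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions ---------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = back
    return out


def gather(t: Tensor, index: np.ndarray, axis: int = 0) -> Tensor:
    """Rows (or slices along ``axis``) of ``t`` at integer ``index``."""
    index = np.asarray(index)
    out = Tensor(np.take(t.data, index, axis=axis), parents=(t,))

    def back(g):
        full = np.zeros_like(t.data)
        if axis == 0:
            np.add.at(full, index, g)
        else:  # pragma: no cover - only axis 0 used in practice
            sl = [slice(None)] * t.data.ndim
            for k, i in enumerate(index):
                sl[axis] = i
                gsl = [slice(None)] * g.ndim
                gsl[axis] = k
                full[tuple(sl)] += g[tuple(gsl)]
        t._accum(full)
    out._backward = back
    return out


def _sorted_starts(segment_ids: np.ndarray, num_segments: int) -> np.ndarray | None:
    """Start offsets for reduceat if ids are sorted with no empty segment."""
    if len(segment_ids) == 0 or segment_ids[0] != 0 or segment_ids[-1] != num_segments - 1:
        return None
    starts = np.searchsorted(segment_ids, np.arange(num_segments))
    if segment_ids[starts].tolist() != list(range(num_segments)):
        return None
    return starts


def _scatter_sum(data: np.ndarray, segment_ids: np.ndarray,
                 num_segments: int) -> np.ndarray:
    starts = _sorted_starts(segment_ids, num_segments)
    if starts is not None:
        return np.add.reduceat(data, starts, axis=0)
    val = np.zeros((num_segments,) + data.shape[1:])
    np.add.at(val, segment_ids, data)
    return val


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` sharing a segment id."""
    segment_ids = np.asarray(segment_ids)
    out = Tensor(_scatter_sum(t.data, segment_ids, num_segments), parents=(t,))
    out._backward = lambda g: t._accum(g[segment_ids])
    return out


def segment_max(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max of rows sharing a segment id; every segment non-empty."""
    segment_ids = np.asarray(segment_ids)
    shape = (num_segments,) + t.data.shape[1:]
    starts = _sorted_starts(segment_ids, num_segments)
    if starts is not None:
        val = np.maximum.reduceat(t.data, starts, axis=0)
    else:
        val = np.full(shape, -np.inf)
        np.maximum.at(val, segment_ids, t.data)
    out = Tensor(val, parents=(t,))

    # ties: gradient routed to the first max occurrence per segment/column
    def back(g):
        is_max = t.data == val[segment_ids]
        order = np.arange(t.data.shape[0]).reshape((-1,) + (1,) * (t.data.ndim - 1))
        first = np.full(shape, np.iinfo(np.int64).max)
        big = np.where(is_max, np.broadcast_to(order, t.data.shape),
                       np.iinfo(np.int64).max)
        np.minimum.at(first, segment_ids, big)
        winner = np.broadcast_to(order, t.data.shape) == first[segment_ids]
        t._accum(np.where(winner, g[segment_ids], 0.0))
    out._backward = back
    return out


def segment_softmax(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``t`` within each segment (along axis 0)."""
    segment_ids = np.asarray(segment_ids)
    shape = (num_segments,) + t.data.shape[1:]
    starts = _sorted_starts(segment_ids, num_segments)
    if starts is not None:
        mx = np.maximum.reduceat(t.data, starts, axis=0)
    else:
        mx = np.full(shape, -np.inf)
        np.maximum.at(mx, segment_ids, t.data)
    e = np.exp(t.data - mx[segment_ids])
    y = e / _scatter_sum(e, segment_ids, num_segments)[segment_ids]
    out = Tensor(y, parents=(t,))

    def back(g):
        dot = _scatter_sum(g * y, segment_ids, num_segments)
        t._accum(y * (g - dot[segment_ids]))
    out._backward = back
    return out


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 rate: float) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


class Adam:
    """Adam optimizer with L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
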