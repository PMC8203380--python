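"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray and records, for every
operation, the parent tensors together with vector-Jacobian-product
closures.  The VJP closures are themselves written in terms of tape
operations, so calling :meth:`Tensor.backward` with ``create_graph=True``
produces gradients that are again differentiable — this is what makes
second-order terms such as the WGAN-GP gradient penalty trainable.

Only the primitives needed by small convolutional GANs are provided;
convolution itself lives in :mod:`cascadegan.nn.conv`.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that suspends tape recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    """float32 by default; float64 ndarrays are preserved so that the
    whole tape can run in double precision when accuracy matters."""
    if isinstance(x, (np.ndarray, np.floating)):
        if x.dtype == np.float64 or x.dtype == np.float32:
            return np.asarray(x)
        return np.asarray(x, dtype=np.float32)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """A node of the computation tape."""

    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Optional[List[Tuple["Tensor", Callable]]] = None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[Tensor] = None
        self._parents = _parents or []

    # -- housekeeping -------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence[Tuple["Tensor", Callable]]) -> "Tensor":
        if _GRAD_ENABLED:
            rec = [(p, fn) for p, fn in parents if p.requires_grad]
            if rec:
                return Tensor(data, requires_grad=True, _parents=rec)
        return Tensor(data)

    # -- backward ------------------------------------------------------

    def _leaf_grads(self, grad: "Tensor", create_graph: bool,
                    keep_ids=frozenset()):
        """Run reverse accumulation; return ({id: grad}, {id: leaf tensor})."""
        topo: List[Tensor] = []
        seen = {id(self)}
        stack = [(self, iter(self._parents))]
        while stack:
            cur, it = stack[-1]
            advanced = False
            for parent, _ in it:
                if id(parent) not in seen and parent._parents:
                    seen.add(id(parent))
                    stack.append((parent, iter(parent._parents)))
                    advanced = True
                    break
                seen.add(id(parent))
            if not advanced:
                topo.append(cur)
                stack.pop()

        grads = {id(self): grad}
        kept = {}
        leaves = {}
        ctx = contextlib.nullcontext() if create_graph else no_grad()
        with ctx:
            for node in reversed(topo):
                g = grads.pop(id(node), None)
                if g is None:
                    continue
                if id(node) in keep_ids:
                    kept[id(node)] = g
                for parent, vjp in node._parents:
                    pg = vjp(g)
                    prev = grads.get(id(parent))
                    grads[id(parent)] = pg if prev is None else add(prev, pg)
                    if not parent._parents:
                        leaves[id(parent)] = parent
        for pid in keep_ids:
            if pid in grads:
                kept[pid] = grads[pid]
        return grads, leaves, kept

    def backward(self, grad: Optional["Tensor"] = None,
                 create_graph: bool = False) -> None:
        """Accumulate gradients of ``self`` into ``.grad`` of all leaves.

        With ``create_graph`` the gradient computation is recorded on the
        tape, so the resulting ``.grad`` tensors can be differentiated
        again.
        """
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = Tensor(np.ones_like(self.data))
        grads, leaves, _ = self._leaf_grads(grad, create_graph)
        ctx = contextlib.nullcontext() if create_graph else no_grad()
        with ctx:
            for pid, parent in leaves.items():
                g = grads.pop(pid, None)
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else add(parent.grad, g)

    # -- operator sugar ------------------------------------------------

    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_(self, -1.0))

    def __pow__(self, c):
        return pow_(self, float(c))

    def __getitem__(self, key):
        return getitem(self, key)

    # convenience methods
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def grad(output: Tensor, inputs: Sequence[Tensor],
         create_graph: bool = False) -> List[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs`` only.

    Unlike :meth:`Tensor.backward`, nothing is accumulated into ``.grad``;
    with ``create_graph`` the returned tensors are differentiable again.
    """
    if output.size != 1:
        raise ValueError("grad() requires a scalar output")
    seed = Tensor(np.ones_like(output.data))
    keep = frozenset(id(t) for t in inputs)
    grads, _, kept = output._leaf_grads(seed, create_graph, keep_ids=keep)
    out = []
    for t in inputs:
        g = kept.get(id(t), grads.get(id(t)))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def _sum_to(g: Tensor, shape: Tuple[int, ...]) -> Tensor:
    """Reduce ``g`` (a broadcasted gradient) back to ``shape``."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    axes = tuple(range(nd))
    axes += tuple(i + nd for i, s in enumerate(shape) if s == 1 and g.shape[i + nd] != 1)
    out = sum_(g, axes, keepdims=True) if axes else g
    return reshape(out, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._make(a.data + b.data,
                        [(a, lambda g: _sum_to(g, a.shape)),
                         (b, lambda g: _sum_to(g, b.shape))])


def neg(a: Tensor) -> Tensor:
    return Tensor._make(-a.data, [(a, neg)])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._make(a.data * b.data,
                        [(a, lambda g: _sum_to(mul(g, b), a.shape)),
                         (b, lambda g: _sum_to(mul(g, a), b.shape))])


def pow_(a: Tensor, c: float) -> Tensor:
    out = Tensor._make(a.data ** c,
                       [(a, lambda g: mul(g, mul(Tensor(np.float32(c)), pow_(a, c - 1.0))))])
    return out


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = Tensor._make(out_data, [(a, lambda g: mul(g, out))])
    return out


def log(a: Tensor) -> Tensor:
    return Tensor._make(np.log(a.data), [(a, lambda g: mul(g, pow_(a, -1.0)))])


def sqrt(a: Tensor) -> Tensor:
    return pow_(a, 0.5)


def tanh(a: Tensor) -> Tensor:
    res = Tensor._make(np.tanh(a.data),
                       [(a, lambda g: mul(g, add(Tensor(1.0), neg(mul(res, res)))))])
    return res


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    res = Tensor._make(data, [(a, lambda g: mul(g, mul(res, add(Tensor(1.0), neg(res)))))])
    return res


def softplus(a: Tensor) -> Tensor:
    """log(1 + e^x), computed stably."""
    data = np.logaddexp(0.0, a.data).astype(a.data.dtype)
    return Tensor._make(data, [(a, lambda g: mul(g, sigmoid(a)))])


def abs_(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))
    return Tensor._make(np.abs(a.data), [(a, lambda g: mul(g, sign))])


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    dt = a.data.dtype
    mask = Tensor(np.where(a.data >= 0, dt.type(1.0), dt.type(slope)))
    return Tensor._make(a.data * mask.data, [(a, lambda g: mul(g, mask))])


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    dt = a.data.dtype
    data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float64).astype(dt)

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            shape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gd = reshape(gd, shape)
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * a.ndim)
        return broadcast_to(gd, a.shape)

    return Tensor._make(np.asarray(data), [(a, vjp)])


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul(sum_(a, axis, keepdims), Tensor(np.asarray(1.0 / n, a.data.dtype)))


def broadcast_to(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    if a.shape == tuple(shape):
        return a
    return Tensor._make(np.ascontiguousarray(np.broadcast_to(a.data, shape)),
                        [(a, lambda g: _sum_to(g, a.shape))])


def reshape(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    return Tensor._make(a.data.reshape(shape),
                        [(a, lambda g: reshape(g, a.shape))])


def transpose(a: Tensor, axes: Optional[Tuple[int, ...]] = None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)),
                        [(a, lambda g: transpose(g, inv))])


def getitem(a: Tensor, key) -> Tensor:
    return Tensor._make(np.ascontiguousarray(a.data[key]),
                        [(a, lambda g: scatter(g, a.shape, key))])


def scatter(g: Tensor, shape: Tuple[int, ...], key) -> Tensor:
    """Place ``g`` into a zero tensor of ``shape`` at ``key`` (inverse of getitem)."""
    out = np.zeros(shape, dtype=g.data.dtype)
    out[key] = g.data
    return Tensor._make(out, [(g, lambda gg: getitem(gg, key))])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + t.shape[axis])
        sl = tuple(sl)
        parents.append((t, (lambda s: lambda g: getitem(g, s))(sl)))
        start += t.shape[axis]
    return Tensor._make(data, parents)


def flip(a: Tensor, axes: Tuple[int, ...]) -> Tensor:
    return Tensor._make(np.ascontiguousarray(np.flip(a.data, axes)),
                        [(a, lambda g: flip(g, axes))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._make(a.data @ b.data,
                        [(a, lambda g: matmul(g, transpose(b))),
                         (b, lambda g: matmul(transpose(a), g))])


def maximum(a: Tensor, b: Tensor) -> Tensor:
    dt = np.result_type(a.data, b.data)
    mask = Tensor((a.data >= b.data).astype(dt))
    inv = Tensor((a.data < b.data).astype(dt))
    return Tensor._make(np.maximum(a.data, b.data),
                        [(a, lambda g: _sum_to(mul(g, mask), a.shape)),
                         (b, lambda g: _sum_to(mul(g, inv), b.shape))])


def pad2d(a: Tensor, p) -> Tensor:
    """Zero-pad the two trailing (spatial) axes.

    ``p`` is either a single symmetric amount or a (top, bottom, left,
    right) tuple.
    """
    if isinstance(p, int):
        t, b, l, r = p, p, p, p
    else:
        t, b, l, r = p
    if t == b == l == r == 0:
        return a
    h, w = a.shape[-2], a.shape[-1]
    out = np.zeros(a.shape[:-2] + (h + t + b, w + l + r), dtype=a.data.dtype)
    key = tuple([slice(None)] * (a.ndim - 2) +
                [slice(t, t + h), slice(l, l + w)])
    out[key] = a.data
    return Tensor._make(out, [(a, lambda g: getitem(g, key))])


def dilate2d(a: Tensor, s: int) -> Tensor:
    """Insert ``s-1`` zeros between spatial samples (transpose of striding)."""
    if s == 1:
        return a
    n, c, h, w = a.shape
    out = np.zeros((n, c, (h - 1) * s + 1, (w - 1) * s + 1), dtype=a.data.dtype)
    out[:, :, ::s, ::s] = a.data
    key = (slice(None), slice(None), slice(None, None, s), slice(None, None, s))
    return Tensor._make(out, [(a, lambda g: getitem(g, key))])
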