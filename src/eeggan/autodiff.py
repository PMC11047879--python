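"""Reverse-mode automatic differentiation on numpy arrays.

A small tensor engine backing the networks in this package.  Every primitive
records vector-Jacobian products that are themselves expressed with tensor
operations, so gradients can be differentiated again — the second-order
derivative needed by the Wasserstein gradient penalty comes out exactly, not
by finite differences.

Only the primitives the models need are provided (elementwise arithmetic,
matmul, reductions, reshaping, sliding-window unfold/fold for 1-D
convolution, and the usual activations).  Data are float64 throughout.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "tensor", "no_grad", "backward", "concat", "stack"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def _grad_mode(enabled: bool):
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = enabled
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        if type(data) is not np.ndarray or data.dtype != np.float64:
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[Tensor], Tensor], ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    @property
    def T(self):
        return transpose(self, None)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        kept_p, kept_v = [], []
        for p, v in zip(parents, vjps):
            if p.requires_grad or p._parents:
                kept_p.append(p)
                kept_v.append(v)
        if kept_p:
            out._parents = tuple(kept_p)
            out._vjps = tuple(kept_v)
            out.requires_grad = True
    return out


# -- broadcasting helpers ----------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce ``g`` to ``shape`` by summing broadcast axes (linear op)."""
    if g.shape == shape:
        return g
    data = g.data
    # sum away extra leading axes
    while data.ndim > len(shape):
        data = data.sum(axis=0)
    axes = tuple(i for i, (a, b) in enumerate(zip(data.shape, shape)) if b == 1 and a != 1)
    if axes:
        data = data.sum(axis=axes, keepdims=True)
    g_shape = g.shape

    def vjp(ct: Tensor) -> Tensor:
        return broadcast_to(ct, g_shape)

    return _make(data, [g], [vjp])


def broadcast_to(t: Tensor, shape: tuple) -> Tensor:
    if t.shape == shape:
        return t
    data = np.broadcast_to(t.data, shape).copy()
    t_shape = t.shape

    def vjp(ct: Tensor) -> Tensor:
        return _sum_to(ct, t_shape)

    return _make(data, [t], [vjp])


# -- arithmetic --------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data
    if not _GRAD_ENABLED:
        return Tensor(out)
    return _make(out, [a, b], [lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)])


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data
    if not _GRAD_ENABLED:
        return Tensor(out)
    return _make(out, [a, b], [lambda g: _sum_to(mul(g, b), a.shape), lambda g: _sum_to(mul(g, a), b.shape)])


def power(x, exponent: float) -> Tensor:
    x = _as_tensor(x)
    e = float(exponent)
    out = x.data ** e

    def vjp(g: Tensor) -> Tensor:
        return mul(g, mul(power(x, e - 1.0), e))

    return _make(out, [x], [vjp])


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def vjp_a(g: Tensor) -> Tensor:
        return _sum_to(matmul(g, _swap_last(b)), a.shape)

    def vjp_b(g: Tensor) -> Tensor:
        return _sum_to(matmul(_swap_last(a), g), b.shape)

    return _make(out, [a, b], [vjp_a, vjp_b])


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


# -- reductions --------------------------------------------------------------

def tsum(x, axis=None, keepdims=False) -> Tensor:
    x = _as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)
    x_shape = x.shape

    def vjp(g: Tensor) -> Tensor:
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(x_shape)), x_shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(a % len(x_shape) for a in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(x_shape))
            g = reshape(g, kshape)
        return broadcast_to(g, x_shape)

    return _make(out, [x], [vjp])


def tmean(x, axis=None, keepdims=False) -> Tensor:
    x = _as_tensor(x)
    if axis is None:
        n = x.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


# -- shape ops ---------------------------------------------------------------

def reshape(x, shape: tuple) -> Tensor:
    x = _as_tensor(x)
    x_shape = x.shape
    return _make(x.data.reshape(shape), [x], [lambda g: reshape(g, x_shape)])


def transpose(x, axes=None) -> Tensor:
    x = _as_tensor(x)
    if axes is None:
        axes = tuple(reversed(range(x.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(x.data.transpose(axes), [x], [lambda g: transpose(g, inv)])


def take(x, idx) -> Tensor:
    """Basic/advanced indexing with scatter-add adjoint."""
    x = _as_tensor(x)
    out = x.data[idx]
    x_shape = x.shape

    def vjp(g: Tensor) -> Tensor:
        return _scatter(g, idx, x_shape)

    return _make(out, [x], [vjp])


def _scatter(g: Tensor, idx, shape: tuple) -> Tensor:
    out = np.zeros(shape)
    np.add.at(out, idx, g.data)

    def vjp(ct: Tensor) -> Tensor:
        return take(ct, idx)

    return _make(out, [g], [vjp])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g: Tensor) -> Tensor:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return take(g, tuple(sl))

        return vjp

    return _make(out, tensors, [make_vjp(i) for i in range(len(tensors))])


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = [reshape(_as_tensor(t), t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)


# -- activations -------------------------------------------------------------

def tanh(x) -> Tensor:
    x = _as_tensor(x)
    y = np.tanh(x.data)

    def vjp(g: Tensor) -> Tensor:
        # rebuild through the graph only when a higher-order graph is wanted
        t = tanh(x) if _GRAD_ENABLED else Tensor(y)
        return mul(g, add(1.0, mul(t, mul(t, -1.0))))

    return _make(y, [x], [vjp])


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))

    def vjp(g: Tensor) -> Tensor:
        s = sigmoid(x) if _GRAD_ENABLED else Tensor(y)
        return mul(g, mul(s, add(1.0, mul(s, -1.0))))

    return _make(y, [x], [vjp])


def exp(x) -> Tensor:
    x = _as_tensor(x)
    return _make(np.exp(x.data), [x], [lambda g: mul(g, exp(x))])


def log(x) -> Tensor:
    x = _as_tensor(x)
    return _make(np.log(x.data), [x], [lambda g: mul(g, power(x, -1.0))])


def sqrt(x) -> Tensor:
    return power(x, 0.5)


def leaky_relu(x, slope: float) -> Tensor:
    """Piecewise-linear activation; the local slope is constant, so the
    second derivative vanishes almost everywhere and double backprop is exact."""
    x = _as_tensor(x)
    m = np.where(x.data > 0, 1.0, slope)
    return mul(x, Tensor(m))


def elu(x, alpha: float = 1.0) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    y = np.where(mask, x.data, alpha * np.expm1(np.minimum(x.data, 0.0)))
    d = np.where(mask, 1.0, y + alpha)  # alpha*exp(x) on the negative side

    def vjp(g: Tensor) -> Tensor:
        return mul(g, Tensor(d))

    return _make(y, [x], [vjp])


# -- backward ----------------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def backward(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
    accumulate: bool = False,
) -> list[Tensor]:
    """Compute d(output)/d(input) for each input.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and can be differentiated again.  With ``accumulate=True`` the
    numeric gradients are also added into each input's ``.grad`` buffer
    (optimizer convention).
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    order = _toposort(output)
    input_ids = {id(i) for i in inputs}
    cot: dict[int, Tensor] = {id(output): grad_output}
    with _grad_mode(create_graph):
        for node in reversed(order):
            g = cot.pop(id(node), None)
            if g is None:
                continue
            if id(node) in input_ids:
                key = ("in", id(node))
                prev = cot.get(key)  # type: ignore[arg-type]
                cot[key] = g if prev is None else add(prev, g)  # type: ignore[index]
            for p, vjp in zip(node._parents, node._vjps):
                pg = vjp(g)
                prev = cot.get(id(p))
                cot[id(p)] = pg if prev is None else add(prev, pg)
    results = []
    for i in inputs:
        g = cot.get(("in", id(i)))  # type: ignore[arg-type]
        if g is None:
            g = Tensor(np.zeros_like(i.data))
        if accumulate:
            if i.grad is None:
                i.grad = np.zeros_like(i.data)
            i.grad += g.data
        results.append(g)
    return results
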