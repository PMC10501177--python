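"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports the small set of tensor operations the SR networks need (elementwise
arithmetic, broadcasting, matmul, gather/scatter for convolution lowering,
reductions, reshapes, leaky ReLU).  Every operation's vector-Jacobian product
is itself written in these operations, so gradients can be differentiated
again — second-order gradients are required to train a critic through the
gradient-penalty term.

Design notes
------------
- Tensors are float64 throughout; the networks here are small and accuracy
  is worth more than speed.
- ``grad(output, inputs, create_graph=...)`` is the functional API;
  ``create_graph=True`` keeps the backward pass differentiable.
- ``leaky_relu``'s backward treats the activation mask as locally constant
  (the function is piecewise linear; its second derivative vanishes almost
  everywhere), which is the standard convention.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "grad",
    "matmul",
    "gather",
    "scatter",
    "leaky_relu",
    "broadcast_to",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *perm):
        if len(perm) == 1 and isinstance(perm[0], (tuple, list)):
            perm = tuple(perm[0])
        return transpose(self, perm)

    def sqrt(self):
        return power(self, 0.5)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp) -> Tensor:
    if grad_enabled() and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra for i, s in enumerate(shape) if s == 1 and g.shape[i + extra] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=False)
    return reshape(g, shape)


def broadcast_to(t: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    out = np.broadcast_to(t.data, shape).copy()
    src_shape = t.shape
    return _make(out, (t,), lambda g: (_unbroadcast(g, src_shape),))


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    sa, sb = a.shape, b.shape
    return _make(
        a.data + b.data, (a, b), lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb))
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    sa, sb = a.shape, b.shape
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), sa), _unbroadcast(mul(g, a), sb)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    sa, sb = a.shape, b.shape
    return _make(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(div(g, b), sa),
            _unbroadcast(mul(g, div(-a, mul(b, b))), sb),
        ),
    )


def power(t: Tensor, p: float) -> Tensor:
    p = float(p)
    return _make(
        t.data**p, (t,), lambda g: (mul(g, mul(_as_tensor(p), power(t, p - 1.0))),)
    )


def leaky_relu(t: Tensor, alpha: float = 0.2) -> Tensor:
    mask = np.where(t.data > 0, 1.0, alpha)
    return _make(t.data * mask, (t,), lambda g: (mul(g, _as_tensor(mask)),))


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def _swap_last(t: Tensor) -> Tensor:
    perm = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return transpose(t, perm)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    sa, sb = a.shape, b.shape
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >= 2D operands")

    def vjp(g: Tensor):
        ga = matmul(g, _swap_last(b))
        gb = matmul(_swap_last(a), g)
        return (_unbroadcast(ga, sa), _unbroadcast(gb, sb))

    return _make(a.data @ b.data, (a, b), vjp)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    src_shape = t.shape
    if axis is None:
        axes = tuple(range(t.ndim))
    elif isinstance(axis, int):
        axes = (axis % t.ndim,)
    else:
        axes = tuple(a % t.ndim for a in axis)
    out = t.data.sum(axis=axes if axis is not None else None, keepdims=keepdims)

    def vjp(g: Tensor):
        if not keepdims:
            kept = [1 if i in axes else s for i, s in enumerate(src_shape)]
            g = reshape(g, tuple(kept))
        return (broadcast_to(g, src_shape),)

    return _make(out, (t,), vjp)


def tmean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        count = t.size
    elif isinstance(axis, int):
        count = t.shape[axis % t.ndim]
    else:
        count = int(np.prod([t.shape[a % t.ndim] for a in axis]))
    return mul(tsum(t, axis=axis, keepdims=keepdims), _as_tensor(1.0 / count))


def reshape(t: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    src_shape = t.shape
    return _make(t.data.reshape(shape), (t,), lambda g: (reshape(g, src_shape),))


def transpose(t: Tensor, perm) -> Tensor:
    perm = tuple(perm)
    inv = tuple(np.argsort(perm))
    return _make(np.transpose(t.data, perm), (t,), lambda g: (transpose(g, inv),))


# ---------------------------------------------------------------------------
# gather / scatter (convolution lowering, zero-padding)
# ---------------------------------------------------------------------------

def gather(t: Tensor, flat_idx: np.ndarray) -> Tensor:
    """``t.reshape(-1)[flat_idx]`` with flat_idx of arbitrary shape."""
    src_shape = t.shape
    src_size = t.size
    out = t.data.reshape(-1)[flat_idx]

    def vjp(g: Tensor):
        return (reshape(scatter(g, flat_idx, src_size), src_shape),)

    return _make(out, (t,), vjp)


def scatter(values: Tensor, flat_idx: np.ndarray, out_size: int) -> Tensor:
    """Zero array of ``out_size`` with ``values`` summed into ``flat_idx``."""
    out = np.bincount(
        flat_idx.reshape(-1), weights=values.data.reshape(-1), minlength=out_size
    ).astype(np.float64)

    def vjp(g: Tensor):
        return (reshape(gather(g, flat_idx.reshape(-1)), values.shape),)

    return _make(out, (values,), vjp)


# ---------------------------------------------------------------------------
# functional gradient
# ---------------------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
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
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own
    computation graph and can be differentiated again.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    if not output.requires_grad:
        raise ValueError("output does not depend on any tensor requiring grad")
    inputs = list(inputs)

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
        for node in reversed(_topo_order(output)):
            g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None and node._vjp is None:
                    grads[id(node)] = g  # leaf: keep for lookup below
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
            if id(node) in (id(t) for t in inputs):
                grads[id(node)] = g  # an input may be an interior node
        out = []
        for t in inputs:
            gt = grads.get(id(t))
            out.append(gt if gt is not None else Tensor(np.zeros(t.shape)))
    return out
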