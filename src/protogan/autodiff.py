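"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains three convolutional networks against a Wasserstein
critic whose gradient-penalty term requires differentiating through a
backward pass (a gradient-of-gradient).  :func:`grad` therefore supports
``create_graph=True``: every vector-Jacobian product is itself written in
terms of the primitives below, so cotangents are ordinary graph nodes and
can be differentiated again.

Convolutions elsewhere in the package are lowered to ``sparse_dot`` with
cached ``scipy.sparse`` im2col operators, which keeps every derivative of
any order a composition of (sparse) matrix products.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "grad",
    "matmul",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "relu",
    "leaky_relu",
    "abs_",
    "sum_",
    "mean_",
    "reshape",
    "transpose",
    "take_rows",
    "ColIndexPlan",
    "gather_cols",
    "scatter_cols",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class _set_grad:
    def __init__(self, mode: bool):
        self._mode = mode

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = self._mode

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    """A numpy array plus the local backward rules that produced it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps", "grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()
        self.grad = None

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

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjps) -> Tensor:
    if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
        t = Tensor(data, requires_grad=True)
        t._parents = tuple(parents)
        t._vjps = tuple(vjps)
        return t
    return Tensor(data)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- arithmetic ---------------------------------------------------------------
#
# Python-number operands take a fast path that leans on numpy's weak
# scalar promotion: wrapping them in arrays would silently upcast float32
# activations to float64.


def _is_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b) -> Tensor:
    if _is_number(b) or _is_number(a):
        if _is_number(a):
            a, b = b, a
        a = _as_tensor(a)
        return _node(a.data + b, (a,), (lambda g: _unbroadcast(g, a.shape),))
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    if _is_number(b):
        return add(a, -b)
    if _is_number(a):
        b = _as_tensor(b)
        return _node(a - b.data, (b,), (lambda g: _unbroadcast(neg(g), b.shape),))
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(neg(g), b.shape)),
    )


def mul(a, b) -> Tensor:
    if _is_number(b) or _is_number(a):
        if _is_number(a):
            a, b = b, a
        a = _as_tensor(a)
        return _node(a.data * b, (a,), (lambda g: _unbroadcast(mul(g, b), a.shape),))
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def div(a, b) -> Tensor:
    if _is_number(b):
        return mul(a, 1.0 / b)
    if _is_number(a):
        b = _as_tensor(b)
        return _node(
            a / b.data,
            (b,),
            (lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),),
        )
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        (
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _node(-a.data, (a,), (lambda g: neg(g),))


def pow_(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _node(
        a.data**p,
        (a,),
        (lambda g: mul(g, mul(p, pow_(a, p - 1.0))),),
    )


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out = _node(np.exp(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), (lambda g: div(g, a),))


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    out = _node(np.sqrt(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: div(mul(g, 0.5), out),)
    return out


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = _node(np.tanh(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, sub(1.0, mul(out, out))),)
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = (a.data > 0).astype(a.data.dtype)
    return _node(a.data * mask, (a,), (lambda g: mul(g, mask),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
    return _node(a.data * factor, (a,), (lambda g: mul(g, factor),))


def abs_(a) -> Tensor:
    a = _as_tensor(a)
    sign = np.sign(a.data)
    return _node(np.abs(a.data), (a,), (lambda g: mul(g, sign),))


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data @ b.data,
        (a, b),
        (
            lambda g: matmul(g, transpose(b, None)),
            lambda g: matmul(transpose(a, None), g),
        ),
    )


# -- reductions / shape -------------------------------------------------------


def _kept_shape(shape, axis):
    if axis is None:
        return (1,) * len(shape)
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(ax % len(shape) for ax in axes)
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        kept = _kept_shape(a.shape, axis)
        g2 = reshape(g, kept) if g.shape != kept else g
        # broadcast back up via addition with a zero constant
        return add(g2, Tensor(np.zeros(a.shape, dtype=a.dtype)))

    return _node(data, (a,), (vjp,))


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax % a.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return div(sum_(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.shape
    return _node(
        a.data.reshape(shape), (a,), (lambda g: reshape(g, orig),)
    )


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return _node(
        a.data.transpose(axes) if axes is not None else a.data.T,
        (a,),
        (lambda g: transpose(g, inv),),
    )


# -- gather / scatter on the leading axis -------------------------------------


def take_rows(a, idx) -> Tensor:
    """``a[idx]`` along the first axis; the adjoint is a scatter-add."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    return _node(a.data[idx], (a,), (lambda g: _scatter_rows(g, idx, a.shape),))


def _scatter_rows(g, idx, shape) -> Tensor:
    g = _as_tensor(g)
    data = np.zeros(shape, dtype=g.dtype)
    np.add.at(data, idx, g.data)
    out = _node(data, (g,), (lambda gg: take_rows(gg, idx),))
    return out


def cast(a, dtype) -> Tensor:
    """Dtype cast; the adjoint casts back (mixed-precision seam)."""
    a = _as_tensor(a)
    orig = a.dtype
    return _node(
        a.data.astype(dtype, copy=False), (a,), (lambda g: cast(g, orig),)
    )


# -- batched gather / scatter-add over flattened feature columns --------------


class ColIndexPlan:
    """A fixed column-selection pattern for batched gather/scatter.

    ``idx`` holds, for each output column, the source column in a
    ``(B, n_cols)`` matrix, with the sentinel value ``n_cols`` selecting
    an implicit zero column (used for padding taps).  The plan caches the
    flattened bincount indices per batch size.  Convolutions are built on
    this: im2col is a pure gather because every patch entry reads exactly
    one input pixel, and its adjoint is the matching scatter-add.
    """

    __slots__ = ("idx", "n_cols", "order", "starts", "uniq")

    def __init__(self, idx, n_cols: int):
        self.idx = np.ascontiguousarray(idx, dtype=np.intp)
        self.n_cols = int(n_cols)
        # scatter support: sort once so the adjoint is gather + reduceat
        self.order = np.argsort(self.idx, kind="stable")
        sorted_idx = self.idx[self.order]
        is_start = np.ones(sorted_idx.size, dtype=bool)
        is_start[1:] = sorted_idx[1:] != sorted_idx[:-1]
        self.starts = np.nonzero(is_start)[0]
        self.uniq = sorted_idx[self.starts]


def gather_cols(x, plan: ColIndexPlan) -> Tensor:
    """``out[b, p] = x[b, plan.idx[p]]`` (zero for the padding sentinel)."""
    x = _as_tensor(x)
    B = x.shape[0]
    xp = np.concatenate(
        [x.data, np.zeros((B, 1), dtype=x.dtype)], axis=1
    )
    return _node(xp[:, plan.idx], (x,), (lambda g: scatter_cols(g, plan),))


def scatter_cols(g, plan: ColIndexPlan) -> Tensor:
    """Adjoint of :func:`gather_cols`: scatter-add columns back."""
    g = _as_tensor(g)
    B = g.shape[0]
    sums = np.add.reduceat(g.data[:, plan.order], plan.starts, axis=1)
    data = np.zeros((B, plan.n_cols), dtype=g.dtype)
    keep = plan.uniq < plan.n_cols  # drop padding-sentinel contributions
    data[:, plan.uniq[keep]] = sums[:, keep]
    return _node(data, (g,), (lambda gg: gather_cols(gg, plan),))


# -- backward -----------------------------------------------------------------


def _toposort(out: Tensor):
    order, seen = [], set()
    stack = [(out, False)]
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
    return order  # parents precede children


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and can be differentiated again.  Inputs unreachable from the
    output get ``None``.
    """
    if output.size != 1:
        raise ValueError("grad() requires a scalar output")
    inputs = list(inputs)
    order = _toposort(output)
    input_ids = {id(t) for t in inputs}
    # a node is 'live' if some input is reachable from it through parents
    live = set(input_ids)
    for node in order:  # parents before children
        if id(node) in live:
            continue
        if any(id(p) in live for p in node._parents):
            live.add(id(node))

    grads = {id(output): Tensor(np.ones_like(output.data))}
    with _set_grad(create_graph):
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or not node._parents:
                if g is not None and id(node) in input_ids:
                    grads[id(node)] = g
                continue
            if id(node) in input_ids:
                grads[id(node)] = g  # keep for return, still propagate
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad or id(p) not in live:
                    continue
                contrib = vjp(g)
                prev = grads.get(id(p))
                grads[id(p)] = contrib if prev is None else add(prev, contrib)
    return [grads.get(id(t)) for t in inputs]
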