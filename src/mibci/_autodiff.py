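"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
expressed through the same differentiable primitives, so calling
:func:`grad` with ``create_graph=True`` yields gradients that can be
differentiated again (needed for second-order meta-gradients).

Design notes
------------
* A :class:`Tensor` records its parents as ``(parent, vjp)`` pairs, where
  ``vjp`` maps the upstream gradient (a Tensor) to the gradient
  contribution for that parent.
* A module-level switch (:func:`no_grad`) disables taping; with
  ``create_graph=False`` the backward pass runs inside ``no_grad`` so the
  returned gradients are constants and the graph is not extended.
* Broadcasting is handled by summing gradient contributions over
  broadcast axes (:func:`_unbroadcast`).
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "grad",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "erf",
    "gelu",
    "relu",
    "sqrt",
    "reshape",
    "swapaxes",
    "transpose",
    "concatenate",
    "stack",
    "pad_last",
    "unfold1d",
    "fold1d",
    "take",
    "scatter_add",
    "maxpool_last",
    "tsum",
    "tmean",
    "softmax",
    "log_softmax",
    "layer_norm",
    "dropout",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def enable_grad():
    """Re-enable graph construction inside a ``no_grad`` region."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = True
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape entries needed for reverse mode."""

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data)
        self.parents = parents if _GRAD_ENABLED else ()
        self.requires_grad = (requires_grad or bool(self.parents)) and _GRAD_ENABLED

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum leading extra axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


def _make(data, entries) -> Tensor:
    """Build an op output; ``entries`` is [(parent, vjp), ...]."""
    if not _GRAD_ENABLED:
        return Tensor(data)
    parents = tuple((p, v) for p, v in entries if p.requires_grad)
    return Tensor(data, parents=parents)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data + b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def power(a, exponent) -> Tensor:
    a = tensor(a)
    if isinstance(exponent, Tensor):  # pragma: no cover - not needed
        raise NotImplementedError("tensor exponents unsupported")
    e = float(exponent)
    return _make(
        a.data ** e,
        [(a, lambda g: mul(g, mul(e, power(a, e - 1.0))))],
    )


def exp(a) -> Tensor:
    a = tensor(a)
    out_data = np.exp(a.data)
    return _make(out_data, [(a, lambda g: mul(g, exp(a)))])


def log(a) -> Tensor:
    a = tensor(a)
    return _make(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = tensor(a)
    return _make(
        np.tanh(a.data),
        [(a, lambda g: mul(g, add(1.0, mul(-1.0, power(tanh(a), 2.0)))))],
    )


def sigmoid(a) -> Tensor:
    a = tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def vjp(g):
        s = sigmoid(a)
        return mul(g, mul(s, add(1.0, mul(-1.0, s))))

    return _make(out_data, [(a, vjp)])


_INV_SQRT_PI = 2.0 / np.sqrt(np.pi)


def erf(a) -> Tensor:
    a = tensor(a)
    return _make(
        _special.erf(a.data),
        [(a, lambda g: mul(g, mul(_INV_SQRT_PI, exp(mul(-1.0, power(a, 2.0))))))],
    )


_INV_SQRT2 = 1.0 / np.sqrt(2.0)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = tensor(a)
    return mul(mul(a, 0.5), add(1.0, erf(mul(a, _INV_SQRT2))))


def relu(a) -> Tensor:
    a = tensor(a)
    mask = (a.data > 0).astype(a.data.dtype)
    return _make(a.data * mask, [(a, lambda g: mul(g, mask))])


# ---------------------------------------------------------------------------
# linear algebra & shape ops
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)

    def vjp_a(g):
        return _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.shape)

    def vjp_b(g):
        return _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.shape)

    return _make(a.data @ b.data, [(a, vjp_a), (b, vjp_b)])


def reshape(a, shape) -> Tensor:
    a = tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def swapaxes(a, ax1, ax2) -> Tensor:
    a = tensor(a)
    return _make(
        np.swapaxes(a.data, ax1, ax2), [(a, lambda g: swapaxes(g, ax1, ax2))]
    )


def transpose(a, axes) -> Tensor:
    a = tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), [(a, lambda g: transpose(g, inv))])


def concatenate(tensors: Sequence, axis=0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)
    entries = []
    for i, t in enumerate(ts):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g, lo=lo, hi=hi):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            return take(g, tuple(idx))

        entries.append((t, vjp))
    return _make(np.concatenate([t.data for t in ts], axis=axis), entries)


def stack(tensors: Sequence, axis=0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    entries = []
    for i, t in enumerate(ts):

        def vjp(g, i=i):
            idx = [slice(None)] * g.ndim
            idx[axis] = i
            return take(g, tuple(idx))

        entries.append((t, vjp))
    return _make(np.stack([t.data for t in ts], axis=axis), entries)


def pad_last(a, left: int, right: int) -> Tensor:
    """Zero-pad the final axis."""
    a = tensor(a)
    width = [(0, 0)] * (a.ndim - 1) + [(left, right)]
    n = a.shape[-1]

    def vjp(g):
        idx = (slice(None),) * (a.ndim - 1) + (slice(left, left + n),)
        return take(g, idx)

    return _make(np.pad(a.data, width), [(a, vjp)])


def take(a, idx) -> Tensor:
    """Numpy-style indexing; gradient scatter-adds back."""
    a = tensor(a)
    return _make(a.data[idx], [(a, lambda g: scatter_add(g, idx, a.shape))])


def scatter_add(g, idx, shape) -> Tensor:
    """Linear adjoint of :func:`take`."""
    g = tensor(g)

    def fwd(data):
        out = np.zeros(shape, dtype=data.dtype)
        np.add.at(out, idx, data)
        return out

    return _make(fwd(g.data), [(g, lambda h: take(h, idx))])


def unfold1d(a, k: int) -> Tensor:
    """Sliding windows of length ``k`` (stride 1) over the last axis.

    ``(..., C, T) -> (..., C*k, T-k+1)`` with windows ordered
    channel-major then tap, matching a dense conv weight ``(out, C*k)``.
    """
    a = tensor(a)
    T = a.shape[-1]
    L = T - k + 1

    def fwd(data):
        win = np.lib.stride_tricks.sliding_window_view(data, k, axis=-1)
        # (..., C, L, k) -> (..., C, k, L) -> (..., C*k, L)
        win = np.swapaxes(win, -1, -2)
        return win.reshape(data.shape[:-2] + (data.shape[-2] * k, L)).copy()

    return _make(fwd(a.data), [(a, lambda g: fold1d(g, k, T))])


def fold1d(g, k: int, T: int) -> Tensor:
    """Linear adjoint of :func:`unfold1d` (overlap-add)."""
    g = tensor(g)
    L = T - k + 1

    def fwd(data):
        C = data.shape[-2] // k
        win = data.reshape(data.shape[:-2] + (C, k, L))
        out = np.zeros(data.shape[:-2] + (C, T), dtype=data.dtype)
        for j in range(k):
            out[..., j : j + L] += win[..., j, :]
        return out

    return _make(fwd(g.data), [(g, lambda h: unfold1d(h, k))])


def maxpool_last(a, size: int) -> Tensor:
    """Non-overlapping max pooling over the last axis (floor division)."""
    a = tensor(a)
    T = a.shape[-1]
    L = T // size
    trimmed = a.data[..., : L * size].reshape(a.shape[:-1] + (L, size))
    arg = trimmed.argmax(axis=-1)
    mask = np.zeros(trimmed.shape, dtype=a.data.dtype)
    np.put_along_axis(mask, arg[..., None], 1.0, axis=-1)

    def vjp(g):
        expanded = mul(reshape(g, g.shape + (1,)), mask)
        flat = reshape(expanded, a.shape[:-1] + (L * size,))
        if L * size == T:
            return flat
        return pad_last(flat, 0, T - L * size)

    return _make(trimmed.max(axis=-1), [(a, vjp)])


# ---------------------------------------------------------------------------
# reductions & compositions
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return mul(g, np.ones(a.shape))
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shape = list(a.shape)
            for ax in axes:
                shape[ax] = 1
            g = reshape(g, shape)
        return mul(g, np.ones(a.shape))

    return _make(out_data, [(a, vjp)])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis=-1) -> Tensor:
    a = tensor(a)
    shift = a.data.max(axis=axis, keepdims=True)  # constant, gradient-free
    e = exp(add(a, -shift))
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def log_softmax(a, axis=-1) -> Tensor:
    a = tensor(a)
    shift = a.data.max(axis=axis, keepdims=True)
    centered = add(a, -shift)
    lse = log(tsum(exp(centered), axis=axis, keepdims=True))
    return add(centered, mul(lse, -1.0))


def layer_norm(a, scale, shift, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then affine scale/shift."""
    a = tensor(a)
    mu = tmean(a, axis=-1, keepdims=True)
    centered = add(a, mul(mu, -1.0))
    var = tmean(mul(centered, centered), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), scale), shift)


def dropout(a, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return tensor(a)
    a = tensor(a)
    mask = (rng.random(a.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return mul(a, mask)


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
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
        for parent, _ in node.parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    create_graph: bool = False,
    output_grad: Tensor | None = None,
):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients remain attached to
    the tape and can themselves be differentiated.
    """
    if output_grad is None:
        seed = Tensor(np.ones_like(output.data))
    else:
        seed = tensor(output_grad)

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    grads: dict[int, Tensor] = {id(output): seed}
    leaf_ids = {id(t) for t in inputs}
    with ctx:
        for node in reversed(_toposort(output)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node.parents:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else add(prev, contrib)
            if id(node) in leaf_ids:
                grads[id(node)] = g  # keep requested leaves

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out
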