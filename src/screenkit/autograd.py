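"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the catalytic-residue network needs:
matrix products, broadcast bias addition, ReLU, column concatenation,
mean pooling over rows, scalar-weighted sums of losses, a class-weighted
two-way softmax cross-entropy, and the hinged triplet margin loss. The
tape is built eagerly; ``backward`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "matmul", "add_bias", "relu", "concat", "mean_rows",
    "weighted_sum", "softmax_cross_entropy", "triplet_margin",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _needs(*tensors):
    return any(t.requires_grad or t._parents for t in tensors)


def _track(data, parents, backward):
    live = [p for p in parents if p.requires_grad or p._parents]
    if not live:
        return Tensor(data)
    return Tensor(data, parents=tuple(parents), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accum(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accum(a.data.T @ g)

    return _track(out, (a, b), backward)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """x (n x d) plus a bias row b (d,) broadcast over rows."""
    out = x.data + b.data

    def backward(g):
        if x.requires_grad or x._parents:
            x._accum(g)
        if b.requires_grad or b._parents:
            b._accum(g.sum(axis=0))

    return _track(out, (x, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        x._accum(g * mask)

    return _track(out, (x,), backward)


def concat(tensors, axis=1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _track(out, tuple(tensors), backward)


def mean_rows(x: Tensor) -> Tensor:
    """Columnwise mean over rows: (n x d) -> (1 x d)."""
    n = x.data.shape[0]
    out = x.data.mean(axis=0, keepdims=True)

    def backward(g):
        x._accum(np.repeat(g / n, n, axis=0))

    return _track(out, (x,), backward)


def weighted_sum(terms) -> Tensor:
    """Sum of (coefficient, scalar tensor) pairs."""
    out = sum(c * t.data for c, t in terms)

    def backward(g):
        for c, t in terms:
            if t.requires_grad or t._parents:
                t._accum(c * g)

    return _track(out, tuple(t for _, t in terms), backward)


def softmax_cross_entropy(logits: Tensor, labels, class_weights=None) -> Tensor:
    """Weighted mean softmax cross-entropy over rows.

    ``labels`` is an (n,) integer array; ``class_weights`` maps each class
    to a sample weight (defaults to 1). The loss is the weighted average of
    per-row negative log-likelihoods.
    """
    z = logits.data
    labels = np.asarray(labels, dtype=int)
    n, k = z.shape
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=float)[labels]
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    p = e / e.sum(axis=1, keepdims=True)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    wsum = w.sum()
    out = float((w * nll).sum() / wsum)

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        grad *= (w / wsum)[:, None]
        logits._accum(g * grad)

    return _track(out, (logits,), backward)


def triplet_margin(za: Tensor, zp, zn, alpha: float = 1.0,
                   hinge: bool = True) -> Tensor:
    """Triplet margin loss max(0, ||za-zp|| - ||za-zn|| + alpha).

    ``zp`` and ``zn`` are plain arrays (cluster centers treated as
    constants); gradients flow only through the anchor.
    """
    zp = np.asarray(zp, dtype=float).reshape(za.data.shape)
    zn = np.asarray(zn, dtype=float).reshape(za.data.shape)
    dp_vec = za.data - zp
    dn_vec = za.data - zn
    dp = float(np.linalg.norm(dp_vec))
    dn = float(np.linalg.norm(dn_vec))
    raw = dp - dn + alpha
    out = max(0.0, raw) if hinge else raw
    active = (raw > 0.0) or not hinge

    def backward(g):
        if not active:
            return
        eps = 1e-12
        grad = dp_vec / max(dp, eps) - dn_vec / max(dn, eps)
        za._accum(g * grad)

    return _track(out, (za,), backward)
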