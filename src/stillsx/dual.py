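"""Vectorized forward-mode differentiation for the analytic model.

The diffraction model is closed-form, so its derivatives are closed-form
too.  Rather than hand-transcribing the chain rule for every one of the
~20 free parameters, this module propagates exact first derivatives
mechanically through the same expressions the likelihoods evaluate: a
:class:`Dual` holds a value array of shape ``S`` and a gradient array of
shape ``S + (P,)`` carrying the partials with respect to ``P`` parameters.
All operations are vectorized over leading axes (typically observations or
pixels), so the cost is a handful of numpy calls per expression, not per
data point.

This is ordinary forward-mode automatic differentiation -- the chain rule
applied to the analytic formulas, exact to machine precision -- and is
entirely distinct from finite differencing (which the tests use as the
independent cross-check).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dual",
    "seed",
    "constant",
    "dstack",
    "dsolve3",
    "dlogdet3",
    "dnorm",
    "ddot",
    "douter",
    "dwhere",
]


class Dual:
    """Value + Jacobian pair.  ``val.shape == S``, ``grad.shape == S + (P,)``."""

    __slots__ = ("val", "grad")
    __array_priority__ = 100  # ensure ndarray + Dual dispatches here

    def __init__(self, val, grad):
        self.val = np.asarray(val, dtype=float)
        self.grad = np.asarray(grad, dtype=float)
        if self.grad.shape[: self.val.ndim] != self.val.shape:
            raise ValueError(
                f"grad shape {self.grad.shape} incompatible with value shape {self.val.shape}"
            )

    @property
    def nparams(self) -> int:
        return self.grad.shape[-1]

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.grad + other.grad)
        other = np.asarray(other, dtype=float)
        val = self.val + other
        grad = np.broadcast_to(self.grad, val.shape + (self.nparams,))
        return Dual(val, grad)

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.grad)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Dual) else -np.asarray(other, float))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(
                self.val * other.val,
                self.grad * other.val[..., None] + other.grad * self.val[..., None],
            )
        other = np.asarray(other, dtype=float)
        return Dual(self.val * other, self.grad * other[..., None])

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv = 1.0 / other.val
            val = self.val * inv
            return Dual(val, (self.grad - other.grad * val[..., None]) * inv[..., None])
        other = np.asarray(other, dtype=float)
        return Dual(self.val / other, self.grad / other[..., None])

    def __rtruediv__(self, other):
        other = np.asarray(other, dtype=float)
        inv = 1.0 / self.val
        val = other * inv
        return Dual(val, -self.grad * (val * inv)[..., None])

    def __pow__(self, p: float):
        val = self.val ** p
        return Dual(val, self.grad * (p * self.val ** (p - 1.0))[..., None])

    # -- elementwise functions -------------------------------------------
    def exp(self):
        val = np.exp(self.val)
        return Dual(val, self.grad * val[..., None])

    def log(self):
        return Dual(np.log(self.val), self.grad / self.val[..., None])

    def sqrt(self):
        val = np.sqrt(self.val)
        return Dual(val, self.grad * (0.5 / val)[..., None])

    # -- reductions / reshaping ------------------------------------------
    def sum(self, axis=None):
        if axis is None:
            return Dual(self.val.sum(), self.grad.reshape(-1, self.nparams).sum(axis=0))
        return Dual(self.val.sum(axis=axis), self.grad.sum(axis=axis))

    def __getitem__(self, idx):
        return Dual(self.val[idx], self.grad[idx])

    def reshape(self, *shape):
        return Dual(self.val.reshape(*shape), self.grad.reshape(*shape, self.nparams))


def constant(val, nparams: int) -> Dual:
    """Lift an array to a Dual with zero derivative."""
    val = np.asarray(val, dtype=float)
    return Dual(val, np.zeros(val.shape + (nparams,)))


def seed(val, index: int, nparams: int) -> Dual:
    """Lift a scalar/array to a Dual that is the ``index``-th parameter."""
    val = np.asarray(val, dtype=float)
    grad = np.zeros(val.shape + (nparams,))
    grad[..., index] = 1.0
    return Dual(val, grad)


def dstack(parts: list[Dual], axis: int = -1) -> Dual:
    """Stack Duals along a new value axis (gradient axis stays last)."""
    ax = axis if axis >= 0 else parts[0].val.ndim + 1 + axis
    return Dual(
        np.stack([p.val for p in parts], axis=ax),
        np.stack([p.grad for p in parts], axis=ax),
    )


def dsolve3(a: Dual, b: Dual) -> Dual:
    """Solve ``A x = b`` for stacked 3x3 systems of Duals.

    ``a.val``: (..., 3, 3); ``b.val``: (..., 3).  Derivative via
    ``dx = A^-1 (db - dA x)``.
    """
    x0 = np.linalg.solve(a.val, b.val[..., None])[..., 0]
    # rhs grad: (..., 3, P)
    rhs = b.grad - np.einsum("...ijp,...j->...ip", a.grad, x0)
    xg = np.linalg.solve(a.val, rhs)
    return Dual(x0, xg)


def dlogdet3(a: Dual) -> Dual:
    """log det of stacked 3x3 SPD Dual matrices; d logdet = tr(A^-1 dA)."""
    sign, logdet = np.linalg.slogdet(a.val)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite in dlogdet3")
    ainv = np.linalg.inv(a.val)
    grad = np.einsum("...ji,...ijp->...p", ainv, a.grad)  # tr(A^-1 dA_p)
    return Dual(logdet, grad)


def dnorm(v: Dual) -> Dual:
    """Euclidean norm over the last value axis of a (..., 3) Dual."""
    n = np.sqrt(np.einsum("...i,...i->...", v.val, v.val))
    grad = np.einsum("...i,...ip->...p", v.val, v.grad) / n[..., None]
    return Dual(n, grad)


def ddot(a: Dual, b: Dual) -> Dual:
    """Dot product over the last value axis."""
    val = np.einsum("...i,...i->...", a.val, b.val)
    grad = np.einsum("...i,...ip->...p", a.val, b.grad) + np.einsum(
        "...i,...ip->...p", b.val, a.grad
    )
    return Dual(val, grad)


def douter(a: Dual, b: Dual) -> Dual:
    """Outer product a_i b_j over the last value axis -> (..., 3, 3)."""
    val = np.einsum("...i,...j->...ij", a.val, b.val)
    grad = np.einsum("...ip,...j->...ijp", a.grad, b.val) + np.einsum(
        "...i,...jp->...ijp", a.val, b.grad
    )
    return Dual(val, grad)


def dwhere(mask: np.ndarray, a: Dual, b: Dual) -> Dual:
    """Elementwise select between two Duals of identical shape."""
    m = np.asarray(mask, dtype=bool)
    return Dual(
        np.where(m, a.val, b.val),
        np.where(m[..., None], a.grad, b.grad),
    )
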