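"""Closed-form reflection prediction chain, evaluated on plain arrays or
dual numbers.

The same expressions -- peak position, broadened peak covariance, Ewald
offset, projected width, integrated-intensity factor, polarization, mean
wavenumber -- are needed three times: as fast vectorized numpy for
prediction, as dual-number arithmetic for exact gradients during fitting,
and one reflection at a time for the public per-reflection API.  This
module implements the chain once over a tiny generic layer that dispatches
between ndarrays and :class:`stillsx.dual.Dual`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamModel
from .crystal import CrystalModel
from .dual import Dual, constant, ddot, dnorm, dsolve3, seed

__all__ = [
    "ReflectionTerms",
    "reflection_terms",
    "crystal_to_theta",
    "theta_to_crystal",
    "theta_to_duals",
    "N_CRYSTAL_PARAMS",
]

#: cell 9 + shape Cholesky 6 + log mosaicity + log strain + log scale + B
N_CRYSTAL_PARAMS = 19

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# generic helpers: work on ndarray or Dual
# ---------------------------------------------------------------------------

def _nparams(*xs) -> int | None:
    for x in xs:
        if isinstance(x, Dual):
            return x.nparams
    return None


def _lift(x, nparams):
    if isinstance(x, Dual) or nparams is None:
        return x
    return constant(np.asarray(x, dtype=float), nparams)


def gdot(a, b):
    p = _nparams(a, b)
    if p is None:
        return np.einsum("...i,...i->...", a, b)
    return ddot(_lift(a, p), _lift(b, p))


def gnorm(v):
    if isinstance(v, Dual):
        return dnorm(v)
    return np.linalg.norm(v, axis=-1)


def gexp(x):
    return x.exp() if isinstance(x, Dual) else np.exp(x)


def gsqrt(x):
    return x.sqrt() if isinstance(x, Dual) else np.sqrt(x)


def gexpand(x, n=1):
    """Append ``n`` trailing value axes (before the gradient axis)."""
    if isinstance(x, Dual):
        v = x.val.reshape(x.val.shape + (1,) * n)
        g = x.grad.reshape(x.val.shape + (1,) * n + (x.nparams,))
        return Dual(v, g)
    return np.reshape(x, np.shape(x) + (1,) * n)


def gouter(a, b):
    p = _nparams(a, b)
    if p is None:
        return np.einsum("...i,...j->...ij", a, b)
    a, b = _lift(a, p), _lift(b, p)
    val = np.einsum("...i,...j->...ij", a.val, b.val)
    grad = np.einsum("...ip,...j->...ijp", a.grad, b.val) + np.einsum(
        "...i,...jp->...ijp", a.val, b.grad
    )
    return Dual(val, grad)


def gsolve3(A, b):
    p = _nparams(A, b)
    if p is None:
        return np.linalg.solve(A, b[..., None])[..., 0]
    return dsolve3(_lift(A, p), _lift(b, p))


def gmatvec_const(R, h):
    """R (3,3) [maybe Dual] times constant rows h (N, 3) -> (N, 3)."""
    if isinstance(R, Dual):
        val = h @ R.val.T
        grad = np.einsum("nj,ijp->nip", h, R.grad)
        return Dual(val, grad)
    return h @ np.asarray(R).T


def gquad_const_mat(S, w):
    """w^T S w with S a (3,3) constant-or-Dual and w (N,3) constant-or-Dual."""
    p = _nparams(S, w)
    if p is None:
        return np.einsum("ni,ij,nj->n", w, S, w)
    S, w = _lift(S, p), _lift(w, p)
    val = np.einsum("ni,ij,nj->n", w.val, S.val, w.val)
    grad = (
        np.einsum("ni,ijp,nj->np", w.val, S.grad, w.val)
        + 2.0 * np.einsum("nip,ij,nj->np", w.grad, S.val, w.val)
    )
    return Dual(val, grad)


# ---------------------------------------------------------------------------
# crystal parameter packing
# ---------------------------------------------------------------------------

_TRIL = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DIAG = {0, 2, 5}  # indices in _TRIL on the diagonal (log-parameterized)


def crystal_to_theta(crystal: CrystalModel) -> np.ndarray:
    """Pack a crystal into the 19-vector used by the optimizers.

    Layout: R row-major (9), lower Cholesky of the shape covariance with
    log diagonal (6), log mosaicity, log strain, log scale, B.
    """
    L = np.linalg.cholesky(crystal.shape_cov + 1e-30 * np.eye(3))
    chol = [np.log(L[i, j]) if k in _DIAG else L[i, j] for k, (i, j) in enumerate(_TRIL)]
    return np.concatenate(
        [
            crystal.R.ravel(),
            chol,
            [
                np.log(max(crystal.mosaicity, 1e-12)),
                np.log(max(crystal.strain, 1e-12)),
                np.log(crystal.scale_a),
                crystal.b_factor,
            ],
        ]
    )


def theta_to_crystal(theta: np.ndarray) -> CrystalModel:
    theta = np.asarray(theta, dtype=float)
    R = theta[:9].reshape(3, 3)
    L = np.zeros((3, 3))
    for k, (i, j) in enumerate(_TRIL):
        v = theta[9 + k]
        L[i, j] = np.exp(v) if k in _DIAG else v
    return CrystalModel(
        R=R,
        shape_cov=L @ L.T,
        mosaicity=float(np.exp(theta[15])),
        strain=float(np.exp(theta[16])),
        scale_a=float(np.exp(theta[17])),
        b_factor=float(theta[18]),
    )


def theta_to_duals(theta: np.ndarray, nparams: int | None = None, offset: int = 0):
    """Seed the 19 crystal parameters as Duals.

    Returns ``(R, shape_cov, mosaicity, strain, scale_a, b_factor)`` where
    the matrix entries carry exact derivatives with respect to the packed
    vector.  ``nparams`` may exceed 19 when the enclosing problem has more
    parameters (e.g. the error model); ``offset`` locates the crystal block.
    """
    theta = np.asarray(theta, dtype=float)
    P = nparams if nparams is not None else N_CRYSTAL_PARAMS
    th = [seed(theta[i], offset + i, P) for i in range(N_CRYSTAL_PARAMS)]
    from .dual import dstack

    R = dstack([dstack(th[3 * i : 3 * i + 3]) for i in range(3)], axis=0)
    Lent: list = [None] * 9
    Lmat = [[None] * 3 for _ in range(3)]
    zero = constant(0.0, P)
    for r in range(3):
        for c in range(3):
            Lmat[r][c] = zero
    for k, (i, j) in enumerate(_TRIL):
        v = th[9 + k]
        Lmat[i][j] = v.exp() if k in _DIAG else v
    L = dstack([dstack(row) for row in Lmat], axis=0)
    # shape_cov = L L^T
    val = L.val @ L.val.T
    grad = np.einsum("ikp,jk->ijp", L.grad, L.val) + np.einsum(
        "ik,jkp->ijp", L.val, L.grad
    )
    shape_cov = Dual(val, grad)
    return R, shape_cov, th[15].exp(), th[16].exp(), th[17].exp(), th[18]


# ---------------------------------------------------------------------------
# the prediction chain
# ---------------------------------------------------------------------------

@dataclass
class ReflectionTerms:
    """Per-reflection closed-form terms (arrays or Duals of shape (N,)).

    ``coef`` is everything multiplying the merged intensity |F|^2:
    ``J0 * a * exp(-B q^2 / 2) * C * factor * g * nu_mean``.
    """

    delta: object  # signed offset from the mean Ewald sphere (nm^-1)
    sigma2: object  # projected variance of delta-k + peak along w_c (nm^-2)
    factor: object  # integrated intensity factor (Ewald-slab overlap)
    partiality: object  # factor / factor at delta = 0
    polarization: object
    nu_mean: object  # expected wavenumber of the reflection (nm^-1)
    nu_var: object  # variance of the wavenumber (nm^-2)
    coef: object
    w_c: object  # (N, 3) outgoing direction of closest sphere approach
    q2: object  # |x|^2


def reflection_terms(
    R,
    shape_cov,
    mosaicity,
    strain,
    scale_a,
    b_factor,
    hkl: np.ndarray,
    beam: BeamModel,
    gain: float = 1.0,
) -> ReflectionTerms:
    """Evaluate the closed-form reflection model for a batch of reflections.

    Parameters may be plain floats/arrays or Duals; ``hkl`` is a constant
    (N, 3) float array.  The outgoing direction used for the projection is
    the closest-sphere-approach direction ``w_c = (nu0 w_in + x)/|.|``,
    the analytic stand-in for the numerically refined optimum.
    """
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    nu0 = beam.nu0
    w_in = beam.w_in

    x = gmatvec_const(R, hkl)  # (N, 3)
    kvec = x + nu0 * w_in[None, :]
    nrm = gnorm(kvec)  # (N,)
    w_c = kvec * gexpand(1.0 / nrm)
    delta = nu0 - nrm
    cos2t = gdot(w_c, np.broadcast_to(w_in, hkl.shape))

    sig_nu = beam.sigma_nu
    var_dk = sig_nu**2 * (1.0 - cos2t) ** 2 + (nu0 * beam.divergence) ** 2 * (
        1.0 - cos2t**2
    )
    wx = gdot(w_c, x)
    q2 = gdot(x, x)
    var_pk = (
        gquad_const_mat(shape_cov, w_c)
        + mosaicity**2 * (q2 - wx**2)
        + strain**2 * wx**2
    )
    sigma2 = var_dk + var_pk

    partiality = gexp(-(delta**2) / (2.0 * sigma2))
    factor = partiality / gsqrt(2.0 * np.pi * sigma2) * (1.0 / nu0**2)

    wn = gdot(w_c, np.broadcast_to(beam.pol_normal, hkl.shape))
    p = beam.polarization_p
    polarization = p * (1.0 - wn**2) + (1.0 - p) * 0.5 * (1.0 + cos2t**2)

    # wavenumber statistics: Gaussian posterior of nu given excitation
    if beam.bandwidth > 0:
        eye = np.broadcast_to(np.eye(3), hkl.shape[:1] + (3, 3))
        xx = gouter(x, x)
        pk_cov = (
            gexpand(mosaicity**2 * q2, 2) * eye
            + gexpand(strain**2 - mosaicity**2, 2) * xx
        )
        pk_cov = pk_cov + shape_cov  # broadcasting (3,3) over (N,3,3)
        if beam.divergence > 0:
            pk_cov = pk_cov + (nu0 * beam.divergence) ** 2 * (
                np.eye(3) - np.outer(w_in, w_in)
            )
        v = w_c - w_in[None, :]
        u = gsolve3(pk_cov, v)
        tau = 1.0 / sig_nu**2 + gdot(v, u)
        nu_mean = (nu0 / sig_nu**2 + gdot(u, x)) / tau
        nu_var = 1.0 / tau
    else:
        P = _nparams(R, shape_cov, mosaicity)
        nfl = hkl.shape[0]
        if P is None:
            nu_mean = np.full(nfl, nu0)
            nu_var = np.zeros(nfl)
        else:
            nu_mean = constant(np.full(nfl, nu0), P)
            nu_var = constant(np.zeros(nfl), P)

    bq = gexp((b_factor * q2) * (-0.5))
    coef = beam.flux * gain * scale_a * bq * polarization * factor * nu_mean
    return ReflectionTerms(
        delta=delta,
        sigma2=sigma2,
        factor=factor,
        partiality=partiality,
        polarization=polarization,
        nu_mean=nu_mean,
        nu_var=nu_var,
        coef=coef,
        w_c=w_c,
        q2=q2,
    )
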