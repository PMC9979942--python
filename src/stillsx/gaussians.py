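"""Closed-form algebra on 3-D Gaussian kernels.

Every distribution in the diffraction model -- the spread of incident
wavevectors, the reciprocal-space peak of a reflection, the detector point
spread -- is carried by the same object: a weighted 3-D Gaussian ("kernel").
Products, convolutions, projections and overlap integrals of Gaussians are
again Gaussian or closed-form scalars, which is what makes pattern
prediction and partiality estimation analytic end to end.

Weights are unitless multipliers; callers attach physical units.  Means are
reciprocal-space vectors (nm^-1) and covariances nm^-2 throughout the
package, but nothing here depends on that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "GaussianKernel",
    "GaussianMixture",
    "DegenerateCovarianceError",
    "symmetric_sqrtm",
    "clip_psd",
    "evaluate",
    "product",
    "convolve",
    "correlated_difference_cov",
    "integrate_product_incoherent",
    "integrate_product_coherent",
    "coherent_amplitude_overlap",
    "project_1d",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateCovarianceError(ValueError):
    """Raised when an operation needs a full-rank covariance but got one
    that is singular.  Carries the null direction for diagnostics."""

    def __init__(self, msg: str, null_direction: np.ndarray | None = None):
        super().__init__(msg)
        self.null_direction = null_direction


def clip_psd(cov: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues of a nominally PSD matrix.

    Numerical noise in differences of covariances can push eigenvalues
    slightly negative; anything below ``-rel_floor * trace`` is a genuine
    error upstream, anything above is clipped to zero.
    """
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    floor = -rel_floor * max(np.trace(cov), np.finfo(float).tiny)
    if np.any(w < floor):
        raise ValueError(
            f"matrix is not PSD within tolerance: min eigenvalue {w.min():g}"
        )
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def symmetric_sqrtm(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below zero (within the PSD clip tolerance) are clipped so
    numerical noise never produces complex roots.
    """
    cov = clip_psd(cov)
    w, v = np.linalg.eigh(cov)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError(f"covariance must be 3x3, got {cov.shape}")
    if not np.allclose(cov, cov.T, rtol=1e-12, atol=1e-12 * max(1.0, abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() < -1e-12 * max(np.trace(cov), np.finfo(float).tiny):
        raise ValueError(f"covariance has negative eigenvalue {w.min():g}")
    return 0.5 * (cov + cov.T)


@dataclass(frozen=True)
class GaussianKernel:
    """A weighted 3-D Gaussian: ``weight * phi(x; mean, cov)``.

    Parameters
    ----------
    weight : float
        Nonnegative multiplier; the kernel integrates to ``weight``.
    mean : (3,) array_like
    cov : (3, 3) array_like
        Symmetric positive-semidefinite.  Rank-deficient covariances are
        legal (e.g. the rank-1 wavelength spread of a beam) but cannot be
        evaluated pointwise.
    """

    weight: float = 1.0
    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cov: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).reshape(3))
        object.__setattr__(self, "cov", _check_cov(self.cov))
        if self.weight < 0:
            raise ValueError("kernel weight must be nonnegative")
        object.__setattr__(self, "weight", float(self.weight))

    def __call__(self, x) -> float:
        return evaluate(self, x)


@dataclass(frozen=True)
class GaussianMixture:
    """Ordered sum of Gaussian kernels; an empty list is the zero density."""

    kernels: tuple[GaussianKernel, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "kernels", tuple(self.kernels))

    def __call__(self, x) -> float:
        return sum(evaluate(k, x) for k in self.kernels)

    def __len__(self) -> int:
        return len(self.kernels)


def _as_kernels(obj) -> tuple[GaussianKernel, ...]:
    if isinstance(obj, GaussianKernel):
        return (obj,)
    if isinstance(obj, GaussianMixture):
        return obj.kernels
    raise TypeError(f"expected GaussianKernel or GaussianMixture, got {type(obj)}")


def _require_nonsingular(cov: np.ndarray, what: str) -> None:
    w, v = np.linalg.eigh(cov)
    scale = max(abs(w).max(), np.finfo(float).tiny)
    if w.min() <= 1e-14 * scale:
        raise DegenerateCovarianceError(
            f"{what}: covariance is singular along direction {v[:, 0]} "
            f"(eigenvalue {w.min():g}, condition number {scale / max(w.min(), np.finfo(float).tiny):g})",
            null_direction=v[:, np.argmin(w)],
        )


def _log_phi(diff: np.ndarray, cov: np.ndarray) -> float:
    """log of the 3-D normal density at offset ``diff`` from the mean."""
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        _require_nonsingular(cov, "log_phi")
    maha = float(diff @ np.linalg.solve(cov, diff))
    return -0.5 * (3.0 * _LOG_2PI + logdet + maha)


def evaluate(k: GaussianKernel, x) -> float:
    """Evaluate ``weight * phi(x; mean, cov)`` at a point.

    Raises
    ------
    DegenerateCovarianceError
        If the covariance is singular (the density is not defined pointwise).
    """
    _require_nonsingular(k.cov, "evaluate")
    x = np.asarray(x, dtype=float).reshape(3)
    return k.weight * float(np.exp(_log_phi(x - k.mean, k.cov)))


def product(a: GaussianKernel, b: GaussianKernel) -> GaussianKernel:
    """Pointwise product of two kernels, again a Gaussian kernel.

    The mean is the precision-weighted mean, the covariance the inverse of
    the summed precisions, and the weight picks up the Gaussian overlap
    factor ``phi(a.mean; b.mean, a.cov + b.cov)`` so that
    ``evaluate(product(a, b), x) == evaluate(a, x) * evaluate(b, x)``.
    """
    s = a.cov + b.cov
    _require_nonsingular(s, "product")
    # cov = A (A+B)^-1 B  is the stable form of (A^-1 + B^-1)^-1 and also
    # valid when one factor is singular.
    s_inv_b = np.linalg.solve(s, b.cov)
    cov = clip_psd(a.cov @ s_inv_b)
    mean = b.mean + (a.mean - b.mean) @ s_inv_b  # = B (A+B)^-1 a.mean + A (A+B)^-1 b.mean
    overlap = np.exp(_log_phi(a.mean - b.mean, s))
    return GaussianKernel(a.weight * b.weight * float(overlap), mean, cov)


def convolve(a: GaussianKernel, b: GaussianKernel) -> GaussianKernel:
    """Convolution: means add, covariances add, weights multiply."""
    return GaussianKernel(a.weight * b.weight, a.mean + b.mean, clip_psd(a.cov + b.cov))


def correlated_difference_cov(cov_out: np.ndarray, cov_in_parallel: np.ndarray) -> np.ndarray:
    """Covariance of the difference of two perfectly correlated Gaussians.

    For correlation 1 the standard deviations subtract, so in matrix form
    the symmetric PSD square roots subtract:
    ``S = sqrtm(cov_out) - sqrtm(cov_in_parallel)``, returned as ``S S^T``
    (re-symmetrized and clipped).  Reduces to ``(sigma_out - sigma_in)^2``
    in one dimension and is exact whenever the two covariances commute.
    """
    s = symmetric_sqrtm(np.asarray(cov_out, float)) - symmetric_sqrtm(
        np.asarray(cov_in_parallel, float)
    )
    return clip_psd(s @ s.T)


def integrate_product_incoherent(a, b) -> float:
    """Integral of the pointwise product of two densities over all space.

    This is the incoherent overlap (intensities add): for single kernels it
    equals the product kernel's weight,
    ``w_a w_b phi(mean_a - mean_b; 0, cov_a + cov_b)``; mixtures distribute
    over all kernel pairs.
    """
    total = 0.0
    for ka in _as_kernels(a):
        for kb in _as_kernels(b):
            s = ka.cov + kb.cov
            _require_nonsingular(s, "integrate_product_incoherent")
            total += ka.weight * kb.weight * float(np.exp(_log_phi(ka.mean - kb.mean, s)))
    return total


def coherent_amplitude_overlap(ka: GaussianKernel, kb: GaussianKernel) -> float:
    """Integral of the product of the kernel *amplitudes* sqrt(w phi).

    sqrt(phi(.; mu, S)) is proportional to a Gaussian with doubled
    covariance; the closed form of the amplitude overlap is

        sqrt(w_a w_b) (8 pi)^(3/2) (det A det B)^(1/4)
            * phi(mu_a - mu_b; 0, 2A + 2B).
    """
    s2 = 2.0 * (ka.cov + kb.cov)
    _require_nonsingular(s2, "coherent overlap")
    da = np.linalg.det(ka.cov)
    db = np.linalg.det(kb.cov)
    pref = (8.0 * np.pi) ** 1.5 * (max(da, 0.0) * max(db, 0.0)) ** 0.25
    return float(
        np.sqrt(ka.weight * kb.weight)
        * pref
        * np.exp(_log_phi(ka.mean - kb.mean, s2))
    )


def integrate_product_coherent(a, b) -> float:
    """Coherent overlap: integrate the amplitudes first, then square.

    Amplitudes of mixture members add before the modulus square, so two-kernel
    mixtures show interference cross terms that the incoherent sum lacks.
    For single kernels the result is the incoherent overlap times the fixed
    scale factor ``(8 pi)^(3/2) sqrt(det A det B / det(A + B))``.
    """
    amp = 0.0
    for ka in _as_kernels(a):
        for kb in _as_kernels(b):
            amp += coherent_amplitude_overlap(ka, kb)
    return amp * amp


def project_1d(k: GaussianKernel, w) -> tuple[float, float, float]:
    """Project a kernel onto a unit direction: (mean, variance, weight)."""
    w = np.asarray(w, dtype=float).reshape(3)
    n = np.linalg.norm(w)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"projection direction must be a unit vector, |w| = {n}")
    var = float(w @ k.cov @ w)
    return float(w @ k.mean), max(var, 0.0), k.weight
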