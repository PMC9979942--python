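"""Closed-form integrated intensities and partialities for still patterns.

The total photon flux of one reflection is the angular integral of the
pixel-wise flux density.  Because a reflection subtends a tiny solid angle,
the family of Ewald spheres can be treated as a planar Gaussian slab near
the peak; integrating the 3-D overlap across the tangent plane at the
optimal outgoing direction collapses the double integral to a 1-D Gaussian
overlap along that direction:

    factor = (1 / nu0^2) * phi(delta; 0, sigma_tot^2),

with ``delta = nu0 - |nu0 w_in + x|`` the distance of the peak from the
mean Ewald sphere and ``sigma_tot^2`` the projected variance of the
delta-k distribution (slab width) plus the peak covariance along the
optimal direction.  The partiality of an observation is this factor
divided by its maximum over rigid reorientations of the crystal, reached
when the peak sits centered in the slab (delta = 0):

    partiality = exp(-delta^2 / (2 sigma_tot^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .beam import BeamModel, delta_k_kernel, polarization_factor
from .crystal import CrystalModel, peak_cov_at

__all__ = [
    "ReflectionPrediction",
    "optimal_direction",
    "integrated_intensity_factor",
    "predicted_intensity",
    "reflection_wavenumber_stats",
    "partiality",
    "predict_reflection",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ReflectionPrediction:
    """Closed-form per-reflection prediction for one still pattern."""

    hkl: tuple
    w_max: np.ndarray
    intensity_factor: float
    predicted_intensity: float
    mean_wavenumber: float
    wavenumber_var: float
    partiality: float
    reachable: bool = True


def _log_flux_density(crystal, beam, x, cov_pk, w):
    dk = delta_k_kernel(beam, w)
    s = dk.cov + cov_pk
    d = dk.mean - x
    sign, logdet = np.linalg.slogdet(s)
    return -0.5 * (float(d @ np.linalg.solve(s, d)) + logdet + 3 * _LOG_2PI)


def _refine_direction(crystal: CrystalModel, beam: BeamModel, hkl,
                      gtol: float = 1e-9, maxiter: int = 200):
    """Maximize the angular flux density; returns (w_max, curvature H, j_max).

    ``H`` is the 2x2 negative Hessian of log j over tangent-plane angles at
    the maximum (finite differences; log j is locally quadratic so these
    are accurate), ``j_max`` the flux density at the optimum.
    """
    x = crystal.peak_position(hkl)
    if np.allclose(x, 0.0):
        raise ValueError("optimal direction undefined for the direct beam (0,0,0)")
    k = beam.nu0 * beam.w_in + x
    w0 = k / np.linalg.norm(k)
    cov_pk = peak_cov_at(crystal, x)
    # orthonormal tangent frame at w0
    t1 = np.cross(w0, [1.0, 0.0, 0.0])
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(w0, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(w0, t1)

    def w_of(u):
        v = w0 + u[0] * t1 + u[1] * t2
        return v / np.linalg.norm(v)

    def neg(u):
        return -_log_flux_density(crystal, beam, x, cov_pk, w_of(u))

    res = minimize(neg, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": maxiter})
    u = np.asarray(res.x, dtype=float)
    # Newton polish: the log flux density is locally quadratic, so a few
    # finite-difference Newton steps drive the curvature-scaled residual
    # step |H^-1 g| (radians on the sphere) to machine level
    hg, hh = 1e-7, 1e-5
    step_norm = np.inf
    H = np.eye(2)
    for _ in range(25):
        g = np.array([
            (neg(u + [hg, 0]) - neg(u - [hg, 0])) / (2 * hg),
            (neg(u + [0, hg]) - neg(u - [0, hg])) / (2 * hg),
        ])
        f0 = neg(u)
        H = np.empty((2, 2))
        H[0, 0] = (neg(u + [hh, 0]) - 2 * f0 + neg(u - [hh, 0])) / hh**2
        H[1, 1] = (neg(u + [0, hh]) - 2 * f0 + neg(u - [0, hh])) / hh**2
        H[0, 1] = H[1, 0] = (
            neg(u + [hh, hh]) - neg(u + [hh, -hh]) - neg(u + [-hh, hh]) + neg(u - [hh, hh])
        ) / (4 * hh**2)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        if neg(u - step) <= f0:
            u = u - step
        else:
            u = u - 0.5 * step
        step_norm = float(np.linalg.norm(step))
        if step_norm < gtol:
            break
    w = w_of(u)
    if step_norm > max(gtol, 1e-8):
        err = RuntimeError(
            f"optimal_direction did not reach stationarity (|Newton step| = {step_norm:g} rad)"
        )
        err.best_iterate = w
        raise err
    # curvature is defined on true angles; the tangent-plane parameterization
    # at u is metrically distorted by |w0 + u| factors, negligible for the
    # sub-milliradian offsets involved
    return w, H, math.exp(-neg(u))


def optimal_direction(
    crystal: CrystalModel,
    beam: BeamModel,
    hkl,
    refine: bool = True,
    gtol: float = 1e-9,
    maxiter: int = 200,
) -> np.ndarray:
    """Outgoing direction of maximal angular flux density for a reflection.

    Starts from the closest-sphere-approach direction
    ``(nu0 w_in + x) / |nu0 w_in + x|`` and, if ``refine`` is on, performs
    a Nelder-Mead + Newton maximization over the two tangent-plane
    coordinates; stationarity (the curvature-scaled Newton step, in
    radians) is verified to ``gtol``, and a failure raises with the best
    iterate attached.
    """
    x = crystal.peak_position(hkl)
    if np.allclose(x, 0.0):
        raise ValueError("optimal direction undefined for the direct beam (0,0,0)")
    if not refine:
        k = beam.nu0 * beam.w_in + x
        return k / np.linalg.norm(k)
    return _refine_direction(crystal, beam, hkl, gtol, maxiter)[0]


def _projected_terms(crystal, beam, x, w):
    """(delta_proj, sigma_tot^2, slab width d) along direction ``w``."""
    dk = delta_k_kernel(beam, w)
    r0 = dk.mean - x
    delta = float(w @ r0)
    var_dk = float(w @ dk.cov @ w)
    var_pk = float(w @ peak_cov_at(crystal, x) @ w)
    return delta, var_dk + var_pk, math.sqrt(max(var_dk, 0.0))


def integrated_intensity_factor(
    crystal: CrystalModel, beam: BeamModel, hkl, w_max: np.ndarray | None = None
) -> float:
    """Angular integral of the flux density of one reflection.

    The tangent-plane integral of the 3-D overlap gives
    ``(1/nu0^2) phi_1(delta; 0, sigma_tot^2)`` -- the 1-D overlap between
    the projected peak and the planar Ewald slab of width ``d`` along the
    optimal direction.  Units: steradian-normalized flux per unit
    structure-factor intensity and incident flux.
    """
    x = crystal.peak_position(hkl)
    peak_extent = math.sqrt(float(np.max(np.linalg.eigvalsh(peak_cov_at(crystal, x)))))
    if peak_extent / beam.nu0 > 0.3:
        import warnings

        warnings.warn(
            "peak angular extent is large; the planar-slab approximation degrades",
            stacklevel=2,
        )
    if w_max is None:
        # Laplace form: same Gaussian structure, but the angular curvature
        # of log j is evaluated exactly at the optimum, which keeps the
        # Ewald-sphere curvature and the direction dependence of the
        # delta-k covariance to second order (the flat-slab projection is
        # its large-radius limit)
        _, H, j_max = _refine_direction(crystal, beam, hkl)
        det = float(np.linalg.det(H))
        if det <= 0:
            raise ValueError("degenerate projected variance")
        return j_max * 2.0 * math.pi / math.sqrt(det)
    delta, s2, _ = _projected_terms(crystal, beam, x, w_max)
    if s2 <= 0:
        raise ValueError("degenerate projected variance")
    return math.exp(-0.5 * delta**2 / s2) / math.sqrt(2 * math.pi * s2) / beam.nu0**2


def reflection_wavenumber_stats(
    crystal: CrystalModel, beam: BeamModel, hkl, w_max: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean and variance of the wavenumber of the integrated reflection."""
    from .pattern import _wavenumber_stats

    if w_max is None:
        w_max = optimal_direction(crystal, beam, hkl)
    x = crystal.peak_position(hkl)
    return _wavenumber_stats(crystal, beam, w_max, x)


def partiality(crystal: CrystalModel, beam: BeamModel, hkl) -> float:
    """Ratio of the reflection's intensity factor to its orientational max.

    The maximum over rigid reorientations of the crystal is attained when
    the peak is rotated onto the Ewald sphere along the geodesic that
    centers it in the slab; the covariance magnitudes are unchanged by the
    small rotation, so the ratio is ``exp(-delta^2 / (2 sigma_tot^2))``.
    Reflections outside the limiting sphere (|x| > 2 nu0) cannot reach the
    diffraction condition and have partiality 0.
    """
    return predict_reflection(crystal, beam, hkl, refine=False).partiality


def predicted_intensity(
    crystal: CrystalModel, beam: BeamModel, hkl, f2: float, gain_g: float = 1.0
) -> float:
    """Expected integrated reading of one reflection.

    ``J0 |F|^2 a exp(-B |x|^2 / 2) C(w_max) factor g nu_mean`` -- linear in
    the structure-factor intensity and in the crystal scale.
    """
    return predict_reflection(crystal, beam, hkl, f2=f2, gain_g=gain_g).predicted_intensity


def predict_reflection(
    crystal: CrystalModel,
    beam: BeamModel,
    hkl,
    f2: float = 1.0,
    gain_g: float = 1.0,
    refine: bool = True,
) -> ReflectionPrediction:
    """Full closed-form prediction of one reflection on one still."""
    x = crystal.peak_position(hkl)
    q = float(np.linalg.norm(x))
    if q > 2.0 * beam.nu0:
        return ReflectionPrediction(
            hkl=tuple(int(i) for i in hkl),
            w_max=np.zeros(3),
            intensity_factor=0.0,
            predicted_intensity=0.0,
            mean_wavenumber=beam.nu0,
            wavenumber_var=0.0,
            partiality=0.0,
            reachable=False,
        )
    factor = None
    if refine:
        try:
            w_max, H, j_max = _refine_direction(crystal, beam, hkl)
            det = float(np.linalg.det(H))
            if det > 0:
                factor = j_max * 2.0 * math.pi / math.sqrt(det)
        except RuntimeError as err:  # keep the best iterate
            w_max = err.best_iterate
    else:
        w_max = optimal_direction(crystal, beam, hkl, refine=False)
    delta, s2, _ = _projected_terms(crystal, beam, x, w_max)
    part = math.exp(-0.5 * delta**2 / s2)
    if factor is None:
        factor = part / math.sqrt(2 * math.pi * s2) / beam.nu0**2
    nu_mean, nu_var = reflection_wavenumber_stats(crystal, beam, hkl, w_max)
    C = polarization_factor(beam, w_max)
    intensity = (
        beam.flux
        * f2
        * crystal.scale_a
        * math.exp(-0.5 * crystal.b_factor * q**2)
        * C
        * factor
        * gain_g
        * nu_mean
    )
    return ReflectionPrediction(
        hkl=tuple(int(i) for i in hkl),
        w_max=w_max,
        intensity_factor=factor,
        predicted_intensity=intensity,
        mean_wavenumber=nu_mean,
        wavenumber_var=nu_var,
        partiality=min(part, 1.0),
        reachable=True,
    )
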