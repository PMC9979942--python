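"""Pixel-wise prediction of still diffraction images.

For every pixel the model evaluates the incoherent overlap between the
delta-k distribution of the beam (viewed toward that pixel, convolved with
the detector point spread) and every significantly excited reciprocal
peak, scales it by polarization, structure-factor intensity and incident
flux, and converts photon flux to an integrating-detector reading via the
expected photon energy.  A two-parameter error model plus a heavy-tailed
outlier mixture turns predictions into per-pixel log-likelihoods that can
be maximized with exact (forward-mode) gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from . import chain
from .beam import BeamModel, delta_k_kernel, polarization_factor
from .crystal import CrystalModel, excited_reflections, peak_cov_at
from .detector import (
    DetectorGeometry,
    Panel,
    direction_derivatives,
    pixel_direction,
    smoothing_covariance,
    solid_angle,
)
from .dual import Dual, constant, seed

__all__ = [
    "ErrorModel",
    "PixelPrediction",
    "pixel_flux",
    "expected_wavenumber",
    "wavenumber_variance",
    "expected_reading",
    "pixel_variance",
    "outlier_logpdf",
    "pixel_loglikelihood",
    "predict_pattern",
    "pattern_loglikelihood",
    "fit_pattern",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: variance inflation when a continuous Gaussian stands in for the discrete
#: (integer-count) reading distribution: the smoothing constant squared,
#: (1/2)^2, in one-count units.
DISCRETIZATION_VARIANCE = 0.25


@dataclass(frozen=True)
class ErrorModel:
    """Two-parameter reading-variance model plus outlier mixture.

    ``variance = alpha * (counting term) + beta * reading^2`` -- a linear
    photon-counting part and a quadratic systematic part -- mixed with a
    super-heavy-tailed outlier density of weight ``epsilon_outlier``.
    """

    alpha: float = 1.0
    beta: float = 0.0
    epsilon_outlier: float = 1.0 / 16.0
    outlier_scale: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not 0.0 <= self.epsilon_outlier < 1.0:
            raise ValueError("epsilon_outlier must lie in [0, 1)")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")


@dataclass(frozen=True)
class PixelPrediction:
    expected_reading: float
    variance: float
    mean_wavenumber: float
    wavenumber_var: float
    flux: float


# ---------------------------------------------------------------------------
# single-pixel building blocks
# ---------------------------------------------------------------------------

def _overlap(mu_dk, cov_dk, x_pk, cov_pk) -> float:
    s = cov_dk + cov_pk
    d = mu_dk - x_pk
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        raise np.linalg.LinAlgError("degenerate joint covariance in pixel overlap")
    return float(np.exp(-0.5 * (d @ np.linalg.solve(s, d) + logdet + 3 * _LOG_2PI)))


def pixel_flux(
    crystal: CrystalModel,
    beam: BeamModel,
    panel: Panel,
    fs: float,
    ss: float,
    structure_intensities: dict,
    hkl_list=None,
    sigma_cutoff: float = 5.0,
    d_min: float = 0.1,
    smoothing: bool = True,
    oversample: int = 1,
    missing: str = "skip",
) -> float:
    """Angular photon flux density toward one pixel (per steradian).

    Sums ``J0 * C * |F|^2 * overlap`` over the excited reflections, where
    the overlap is the incoherent integral of the delta-k kernel of the
    pixel direction (optionally convolved with the detector point spread)
    against each reciprocal peak kernel.
    """
    w = pixel_direction(panel, fs, ss)
    if hkl_list is None:
        hkl_list = sorted(excited_reflections(crystal, beam, sigma_cutoff, d_min))
    dk = delta_k_kernel(beam, w)
    cov_dk = dk.cov
    if smoothing:
        cov_dk = cov_dk + beam.nu0**2 * smoothing_covariance(panel, fs, ss, oversample)
    C = polarization_factor(beam, w)
    total = 0.0
    for hkl in hkl_list:
        key = tuple(int(i) for i in hkl)
        if key not in structure_intensities:
            if missing == "error":
                raise KeyError(f"no structure intensity for reflection {key}")
            continue
        f2 = structure_intensities[key]
        if f2 < 0:
            raise ValueError(f"negative structure intensity for {key}")
        x = crystal.peak_position(key)
        total += beam.flux * C * f2 * _overlap(dk.mean, cov_dk, x, peak_cov_at(crystal, x))
    return total


def _wavenumber_stats(
    crystal: CrystalModel,
    beam: BeamModel,
    w: np.ndarray,
    x: np.ndarray,
    extra_cov: np.ndarray | None = None,
) -> tuple[float, float]:
    """Posterior mean/variance of the wavenumber given arrival along ``w``.

    Prior ``nu ~ N(nu0, sigma_nu^2)``; the excitation weight of a photon of
    wavenumber ``nu`` is the peak overlap of ``delta_k = nu (w - w_in)``
    marginalized over divergence (and the point spread, if given).  In the
    nonsingular case this equals projecting the joint kernel onto the beam
    direction and rescaling by the Ewald shear factor ``1/(1 - cos 2theta)``;
    this form stays exact in the monochromatic limit.
    """
    if beam.bandwidth == 0:
        return beam.nu0, 0.0
    v = w - beam.w_in
    cov = peak_cov_at(crystal, x)
    if beam.divergence > 0:
        cov = cov + (beam.nu0 * beam.divergence) ** 2 * (
            np.eye(3) - np.outer(beam.w_in, beam.w_in)
        )
    if extra_cov is not None:
        cov = cov + extra_cov
    u = np.linalg.solve(cov, v)
    s2 = beam.sigma_nu**2
    tau = 1.0 / s2 + float(v @ u)
    mean = (beam.nu0 / s2 + float(u @ x)) / tau
    return mean, 1.0 / tau


def expected_wavenumber(
    crystal: CrystalModel, beam: BeamModel, panel: Panel, fs: float, ss: float, hkl
) -> float:
    """Mean wavenumber of photons reaching one pixel via one reflection."""
    w = pixel_direction(panel, fs, ss)
    x = crystal.peak_position(hkl)
    return _wavenumber_stats(crystal, beam, w, x)[0]


def wavenumber_variance(
    crystal: CrystalModel, beam: BeamModel, panel: Panel, fs: float, ss: float, hkl
) -> float:
    """Variance of the per-pixel wavenumber; zero for a monochromatic beam."""
    w = pixel_direction(panel, fs, ss)
    x = crystal.peak_position(hkl)
    return _wavenumber_stats(crystal, beam, w, x)[1]


def expected_reading(
    pred_flux: float, mean_wavenumber: float, solid_angle_sr: float, gain_g: float
) -> float:
    """Integrating-detector reading: counts = g * nu_mean * flux * Omega."""
    return gain_g * mean_wavenumber * pred_flux * solid_angle_sr


def pixel_variance(
    em: ErrorModel,
    expected: float,
    mean_wavenumber: float,
    wavenumber_var: float,
    gain_g: float = 1.0,
) -> float:
    """Reading variance from the two-parameter error model.

    The counting part is compound Poisson: a reading ``r = g sum_i nu_i``
    over a Poisson number of photons has variance ``g^2 E[N] E[nu^2]``,
    i.e. ``g r (nu_mean^2 + nu_var) / nu_mean`` -- the polychromatic
    inflation enters through the second moment of the photon energy.  The
    systematic part scales quadratically with the reading.
    """
    counting = gain_g * max(expected, 0.0) * (
        (mean_wavenumber**2 + wavenumber_var) / mean_wavenumber
    )
    return em.alpha * counting + em.beta * expected**2


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_OUTLIER_X0 = 2.0
_OUTLIER_LOGNORM = math.log(math.log(2.0) / 2.0)


def outlier_logpdf(x, scale: float = 1.0):
    """Log density of the smoothed heavy-tailed outlier distribution.

    A smoothed version of the universal-prior-style density
    ``rho(t) = (ln 2 / 2) / ((|t| + 2) ln^2(|t| + 2))`` with an analytic
    normalization (it integrates to one exactly); ``scale`` sets the count
    unit.  The asymptotic decay is ``1/(x ln^2 x)`` -- slower than any
    power beyond the first -- so even extreme readings keep finite
    log-likelihood.
    """
    t = np.abs(np.asarray(x, dtype=float)) / scale + _OUTLIER_X0
    return _OUTLIER_LOGNORM - np.log(t) - 2.0 * np.log(np.log(t)) - math.log(scale)


def pixel_loglikelihood(measured: float, pred: PixelPrediction, em: ErrorModel) -> float:
    """Log of the Gaussian + outlier mixture density for one pixel reading.

    The Gaussian stands in for the discrete count distribution, so its
    variance is inflated by the discretization constant (1/2)^2; the
    outlier component guarantees a finite value for arbitrarily wild
    readings (dead or hot pixels).
    """
    var = pred.variance + DISCRETIZATION_VARIANCE
    if var <= 0:
        raise ValueError("pixel variance must be positive")
    lg = -0.5 * ((measured - pred.expected_reading) ** 2 / var + math.log(2 * math.pi * var))
    lo = float(outlier_logpdf(measured, em.outlier_scale))
    eps = em.epsilon_outlier
    if eps == 0:
        return lg
    m = max(lg + math.log1p(-eps), lo + math.log(eps))
    return m + math.log(
        math.exp(lg + math.log1p(-eps) - m) + math.exp(lo + math.log(eps) - m)
    )


# ---------------------------------------------------------------------------
# full-pattern prediction
# ---------------------------------------------------------------------------

def _panel_center_of(panel: Panel, w: np.ndarray):
    """Intersect the ray along ``w`` with the panel plane -> (fs, ss, t)."""
    A = np.column_stack([panel.D, -w])
    try:
        sol = np.linalg.solve(A, -panel.origin_o)
    except np.linalg.LinAlgError:
        return None
    fs, ss, t = sol
    if t <= 0:
        return None
    return fs - 0.5, ss - 0.5, t  # center-based pixel coordinates


def _touched_pixels(
    crystal: CrystalModel,
    beam: BeamModel,
    panel: Panel,
    hkl,
    sigma_ellipse: float = 4.0,
):
    """Pixels within the n-sigma ellipse of one reflection on one panel.

    The 3-D covariance of the observable spot (product of the delta-k and
    peak kernels plus the point spread) is pushed onto detector coordinates
    through the pseudo-inverse of the direction Jacobian scaled by nu0.
    """
    x = crystal.peak_position(hkl)
    k = beam.nu0 * beam.w_in + x
    nk = np.linalg.norm(k)
    if nk < 1e-12:
        return None
    w = k / nk
    hit = _panel_center_of(panel, w)
    if hit is None:
        return None
    fs_c, ss_c, _ = hit
    if not (-20 <= fs_c <= panel.n_fs + 20 and -20 <= ss_c <= panel.n_ss + 20):
        return None
    dk = delta_k_kernel(beam, w)
    cov_pk = peak_cov_at(crystal, x)
    s = dk.cov + cov_pk
    prod_cov = cov_pk - cov_pk @ np.linalg.solve(s, cov_pk)  # product-kernel cov
    prod_cov = prod_cov + beam.nu0**2 * smoothing_covariance(
        panel, max(0.0, min(fs_c, panel.n_fs - 1.0)), max(0.0, min(ss_c, panel.n_ss - 1.0))
    )
    J = beam.nu0 * direction_derivatives(panel, fs_c, ss_c)  # (3, 2)
    pinv = np.linalg.pinv(J)
    cov2 = clip_psd_2(pinv @ prod_cov @ pinv.T)
    sig_fs = math.sqrt(max(cov2[0, 0], 1e-12))
    sig_ss = math.sqrt(max(cov2[1, 1], 1e-12))
    lo_fs = max(0, int(math.floor(fs_c - sigma_ellipse * sig_fs - 1)))
    hi_fs = min(panel.n_fs - 1, int(math.ceil(fs_c + sigma_ellipse * sig_fs + 1)))
    lo_ss = max(0, int(math.floor(ss_c - sigma_ellipse * sig_ss - 1)))
    hi_ss = min(panel.n_ss - 1, int(math.ceil(ss_c + sigma_ellipse * sig_ss + 1)))
    if lo_fs > hi_fs or lo_ss > hi_ss:
        return None
    fs_idx, ss_idx = np.meshgrid(
        np.arange(lo_fs, hi_fs + 1), np.arange(lo_ss, hi_ss + 1), indexing="ij"
    )
    return fs_idx.ravel(), ss_idx.ravel(), (fs_c, ss_c), cov2


def clip_psd_2(m: np.ndarray) -> np.ndarray:
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    return (v * np.clip(w, 0.0, None)) @ v.T


def _panel_pair_readings(
    crystal: CrystalModel,
    beam: BeamModel,
    panel: Panel,
    structure_intensities: dict,
    hkl_list,
    oversample: int,
    sigma_ellipse: float,
):
    """Vectorized per-(pixel, reflection) signal terms for one panel.

    Returns flat pixel indices, per-pair reading contributions and the
    per-pair photon-count / wavenumber terms needed for variance
    bookkeeping (all numpy, no gradients).
    """
    pix_idx: list[np.ndarray] = []
    readings: list[np.ndarray] = []
    n_photon: list[np.ndarray] = []
    nu_mean_l: list[np.ndarray] = []
    nu_var_l: list[np.ndarray] = []
    for hkl in hkl_list:
        key = tuple(int(i) for i in hkl)
        f2 = structure_intensities.get(key)
        if f2 is None:
            continue
        touched = _touched_pixels(crystal, beam, panel, key, sigma_ellipse)
        if touched is None:
            continue
        fs_idx, ss_idx, _, _ = touched
        x = crystal.peak_position(key)
        cov_pk = peak_cov_at(crystal, x)
        scale = (
            beam.flux
            * f2
            * crystal.scale_a
            * math.exp(-0.5 * crystal.b_factor * float(x @ x))
        )
        nus = np.zeros(fs_idx.size)
        nuv = np.zeros(fs_idx.size)
        photons = np.zeros(fs_idx.size)
        s = oversample
        subs = (np.arange(s) + 0.5) / s - 0.5  # offsets of subpixel centers
        for i, (fs, ss) in enumerate(zip(fs_idx, ss_idx)):
            # average the smoothed density over s^2 subpixel samples, each
            # with the point spread shrunk to the subpixel extent
            acc_photon = 0.0
            acc_nu = 0.0
            acc_e2 = 0.0
            for dfs in subs:
                for dss in subs:
                    fss, sss = fs + dfs, ss + dss
                    w = pixel_direction(panel, fss, sss)
                    dk = delta_k_kernel(beam, w)
                    sm = beam.nu0**2 * smoothing_covariance(panel, fss, sss, s)
                    ov = _overlap(dk.mean, dk.cov + sm, x, cov_pk)
                    om = solid_angle(panel, fss, sss) / s**2
                    C = polarization_factor(beam, w)
                    ph = scale * C * ov * om
                    nu_m, nu_v = _wavenumber_stats(crystal, beam, w, x, extra_cov=sm)
                    acc_photon += ph
                    acc_nu += ph * nu_m
                    acc_e2 += ph * (nu_m**2 + nu_v)
            photons[i] = acc_photon
            if acc_photon > 0:
                nus[i] = acc_nu / acc_photon
                nuv[i] = max(acc_e2 / acc_photon - nus[i] ** 2, 0.0)
            else:
                nus[i] = beam.nu0
        reading = panel.gain_g * nus * photons
        pix_idx.append(fs_idx * panel.n_ss + ss_idx)
        readings.append(reading)
        n_photon.append(photons)
        nu_mean_l.append(nus)
        nu_var_l.append(nuv)
    if not pix_idx:
        z = np.zeros(0)
        return z.astype(int), z, z, z, z
    return (
        np.concatenate(pix_idx).astype(int),
        np.concatenate(readings),
        np.concatenate(n_photon),
        np.concatenate(nu_mean_l),
        np.concatenate(nu_var_l),
    )


def predict_pattern(
    crystal: CrystalModel,
    beam: BeamModel,
    detector: DetectorGeometry,
    structure_intensities: dict,
    background: dict | None = None,
    sigma_cutoff: float = 4.0,
    d_min: float = 0.1,
    oversample: int = 1,
    sigma_ellipse: float = 4.0,
):
    """Predict expected readings for every pixel of every panel.

    Only pixels inside the projected ``sigma_ellipse`` Mahalanobis ellipse
    of an excited reflection receive signal; everything else is background.
    Returns ``{panel name: image array (n_fs, n_ss)}``.
    """
    hkl_list = sorted(excited_reflections(crystal, beam, sigma_cutoff, d_min))
    out = {}
    for panel in detector:
        img = np.zeros((panel.n_fs, panel.n_ss))
        if background is not None and panel.name in background:
            img += np.asarray(background[panel.name], dtype=float)
        idx, readings, _, _, _ = _panel_pair_readings(
            crystal, beam, panel, structure_intensities, hkl_list, oversample, sigma_ellipse
        )
        np.add.at(img.ravel(), idx, readings)
        out[panel.name] = img
    return out


# ---------------------------------------------------------------------------
# pattern likelihood and fitting (exact gradients via dual numbers)
# ---------------------------------------------------------------------------

FIT_GROUPS = ("cell", "shape", "mosaicity", "strain", "scale", "b_factor", "error_model")


def _pack_pattern_params(crystal: CrystalModel, em: ErrorModel) -> np.ndarray:
    return np.concatenate(
        [chain.crystal_to_theta(crystal), [math.log(em.alpha), math.log(max(em.beta, 1e-12))]]
    )


def _group_indices() -> dict:
    return {
        "cell": list(range(0, 9)),
        "shape": list(range(9, 15)),
        "mosaicity": [15],
        "strain": [16],
        "scale": [17],
        "b_factor": [18],
        "error_model": [19, 20],
    }


def _collect_pairs(
    crystal: CrystalModel,
    beam: BeamModel,
    panel: Panel,
    structure_intensities: dict,
    hkl_list,
    oversample: int,
    sigma_ellipse: float,
):
    """Constant per-(pixel, reflection) geometry for the likelihood chain."""
    pair_pix: list[int] = []
    pair_hkl: list[tuple] = []
    pair_w: list[np.ndarray] = []
    pair_sm: list[np.ndarray] = []
    pair_om: list[float] = []
    pair_f2: list[float] = []
    for hkl in hkl_list:
        key = tuple(int(i) for i in hkl)
        f2 = structure_intensities.get(key)
        if f2 is None:
            continue
        touched = _touched_pixels(crystal, beam, panel, key, sigma_ellipse)
        if touched is None:
            continue
        fs_idx, ss_idx, _, _ = touched
        for fs, ss in zip(fs_idx, ss_idx):
            pair_pix.append(int(fs) * panel.n_ss + int(ss))
            pair_hkl.append(key)
            pair_w.append(pixel_direction(panel, fs, ss))
            pair_sm.append(beam.nu0**2 * smoothing_covariance(panel, fs, ss, oversample))
            pair_om.append(solid_angle(panel, fs, ss))
            pair_f2.append(float(f2))
    return (
        np.array(pair_pix, dtype=int),
        np.array(pair_hkl, dtype=float).reshape(-1, 3),
        np.array(pair_w, dtype=float).reshape(-1, 3),
        np.array(pair_sm, dtype=float).reshape(-1, 3, 3),
        np.array(pair_om, dtype=float),
        np.array(pair_f2, dtype=float),
    )


def _dual_bincount(idx: np.ndarray, d: Dual, n: int) -> Dual:
    val = np.bincount(idx, weights=d.val, minlength=n)
    grad = np.zeros((n, d.nparams))
    np.add.at(grad, idx, d.grad)
    return Dual(val, grad)


def pattern_loglikelihood(
    theta: np.ndarray,
    pairs,
    measured: np.ndarray,
    background: np.ndarray,
    beam: BeamModel,
    gain: float,
    em_template: ErrorModel,
    with_grad: bool = True,
):
    """Total pattern log-likelihood (and gradient) at packed parameters.

    ``pairs`` is the output of :func:`_collect_pairs`; ``measured`` and
    ``background`` are flat per-pixel arrays.  Background enters the
    reading additively and is treated as carrying photons of the mean
    wavenumber.
    """
    idx, hkl, w_dir, sm_cov, omega, f2 = pairs
    P = chain.N_CRYSTAL_PARAMS + 2
    npix = measured.size
    nu0, w_in = beam.nu0, beam.w_in

    if with_grad:
        R, shape_cov, sigm, sigs, a, B = chain.theta_to_duals(theta, nparams=P)
        alpha = seed(theta[19], 19, P).exp()
        beta = seed(theta[20], 20, P).exp()
    else:
        c = chain.theta_to_crystal(theta[:19])
        R, shape_cov, sigm, sigs, a, B = (
            c.R,
            c.shape_cov,
            c.mosaicity,
            c.strain,
            c.scale_a,
            c.b_factor,
        )
        alpha, beta = math.exp(theta[19]), math.exp(theta[20])

    from .chain import gdot, gexp, gexpand, gouter, gquad_const_mat, gsolve3, gsqrt, gmatvec_const, gnorm

    if idx.size:
        x = gmatvec_const(R, hkl)  # (M, 3)
        q2 = gdot(x, x)
        xx = gouter(x, x)
        eye = np.broadcast_to(np.eye(3), (idx.size, 3, 3))
        pk_cov = (
            gexpand(sigm**2 * q2, 2) * eye
            + gexpand(sigs**2 - sigm**2, 2) * xx
            + shape_cov
        )
        # delta-k kernel toward the pixel direction (constant w)
        v = w_dir - w_in[None, :]
        mu_dk = nu0 * v
        sig_nu2 = (nu0 * beam.bandwidth) ** 2
        cov_dk = sig_nu2 * np.einsum("ni,nj->nij", v, v)
        if beam.divergence > 0:
            cov_dk = cov_dk + (nu0 * beam.divergence) ** 2 * (
                np.eye(3) - np.outer(w_in, w_in)
            )
        S = pk_cov + (cov_dk + sm_cov)
        d = mu_dk - x
        u = gsolve3(S, d)
        maha = gdot(d, u)
        if with_grad:
            from .dual import dlogdet3

            logdet = dlogdet3(S if isinstance(S, Dual) else constant(S, P))
        else:
            _, logdet = np.linalg.slogdet(S)
        overlap = gexp((maha + logdet + 3.0 * _LOG_2PI) * (-0.5))
        Cpol = np.array([polarization_factor(beam, wi) for wi in w_dir])
        bq = gexp((B * q2) * (-0.5))
        flux = (beam.flux * f2 * Cpol * omega) * (a * bq * overlap)
        # wavenumber stats per pair
        if beam.bandwidth > 0:
            cov_nu = pk_cov + (cov_dk - sig_nu2 * np.einsum("ni,nj->nij", v, v)) + sm_cov
            uv = gsolve3(cov_nu, v)
            tau = 1.0 / sig_nu2 + gdot(v, uv)
            nu_mean = (nu0 / sig_nu2 + gdot(uv, x)) / tau
            nu_var = 1.0 / tau
        else:
            nu_mean = constant(np.full(idx.size, nu0), P) if with_grad else np.full(idx.size, nu0)
            nu_var = constant(np.zeros(idx.size), P) if with_grad else np.zeros(idx.size)
        photons = flux  # photons per pair (flux density * solid angle folded in)
        pair_reading = gain * (nu_mean * photons)
        pair_e2 = (nu_mean**2 + nu_var) * photons  # photon-energy second moment

        if with_grad:
            reading = _dual_bincount(idx, pair_reading, npix) + background
            e2 = _dual_bincount(idx, pair_e2, npix) + background * (nu0 / gain)
        else:
            reading = np.bincount(idx, weights=pair_reading, minlength=npix) + background
            e2 = np.bincount(idx, weights=pair_e2, minlength=npix) + background * (
                nu0 / gain
            )
    else:
        if with_grad:
            reading = constant(background.copy(), P)
            e2 = constant(background * (nu0 / gain), P)
        else:
            reading = background.copy()
            e2 = background * (nu0 / gain)

    # counting variance: g^2 * (photon count) * E[photon energy^2]; the
    # background is treated as photons at the mean wavenumber
    counting = gain**2 * e2
    var = alpha * counting + beta * reading**2 + DISCRETIZATION_VARIANCE

    resid = reading - measured
    logvar = var.log() if isinstance(var, Dual) else np.log(var)
    lg = (resid**2 / var + logvar + _LOG_2PI) * (-0.5)
    em = em_template
    lo = outlier_logpdf(measured, em.outlier_scale)
    eps = em.epsilon_outlier
    if eps == 0:
        total = lg.sum()
    else:
        # log((1-eps) exp(lg) + eps exp(lo)), stable in the Gaussian tail
        if isinstance(lg, Dual):
            shift = np.maximum(lg.val + math.log1p(-eps), lo + math.log(eps))
            g_t = gexp(lg + (math.log1p(-eps) - shift))
            mix = g_t + np.exp(lo + math.log(eps) - shift)
            total = (mix.log() + shift).sum()
        else:
            shift = np.maximum(lg + math.log1p(-eps), lo + math.log(eps))
            total = np.sum(
                np.log(np.exp(lg + math.log1p(-eps) - shift) + np.exp(lo + math.log(eps) - shift))
                + shift
            )
    if isinstance(total, Dual):
        return float(total.val), total.grad.copy()
    return float(total), None


def fit_pattern(
    images: dict,
    detector: DetectorGeometry,
    crystal: CrystalModel,
    beam: BeamModel,
    structure_intensities: dict,
    background: dict | None = None,
    em: ErrorModel | None = None,
    fixed: tuple = (),
    sigma_cutoff: float = 4.0,
    d_min: float = 0.1,
    oversample: int = 1,
    sigma_ellipse: float = 5.0,
    maxiter: int = 200,
    gtol: float = 1e-8,
):
    """Local maximum-likelihood refinement of a still pattern model.

    Maximizes the summed per-pixel mixture log-likelihood over the crystal
    parameters (cell, shape covariance, mosaicity, strain, scale, B) and
    the error model, with exact forward-mode gradients.  ``fixed`` names
    parameter groups to hold at their initial values (any of
    ``FIT_GROUPS``).  Source and detector geometry are fixed.

    Returns ``(crystal, error_model, diagnostics)``.
    """
    em = em or ErrorModel()
    for g in fixed:
        if g not in FIT_GROUPS:
            raise ValueError(f"unknown parameter group {g!r}")
    hkl_list = sorted(excited_reflections(crystal, beam, sigma_cutoff, d_min))

    all_pairs = []
    measured_l = []
    background_l = []
    gains = []
    for panel in detector:
        img = np.asarray(images[panel.name], dtype=float)
        bg = (
            np.asarray(background[panel.name], dtype=float).ravel()
            if background is not None and panel.name in background
            else np.zeros(img.size)
        )
        pairs = _collect_pairs(
            crystal, beam, panel, structure_intensities, hkl_list, oversample, sigma_ellipse
        )
        all_pairs.append(pairs)
        measured_l.append(img.ravel())
        background_l.append(bg)
        gains.append(panel.gain_g)

    theta0 = _pack_pattern_params(crystal, em)
    free = np.ones(theta0.size, dtype=bool)
    gi = _group_indices()
    for g in fixed:
        free[gi[g]] = False

    # diagonal preconditioner: typical parameter variations (the likelihood
    # is vastly stiffer in the cell entries than in the log-parameters)
    scales = np.empty(theta0.size)
    scales[:9] = 1e-3 * max(float(np.abs(theta0[:9]).max()), 1e-6)
    scales[9:15] = [0.3 if k in (0, 2, 5) else 1e-3 for k in range(6)]
    scales[15:19] = [0.3, 0.3, 0.2, 0.02]
    scales[19:] = 0.3

    def objective_at(th):
        total = 0.0
        grad = np.zeros(theta0.size)
        for pairs, meas, bg, g in zip(all_pairs, measured_l, background_l, gains):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                ll, gr = pattern_loglikelihood(th, pairs, meas, bg, beam, g, em)
            total += ll
            grad += gr
        if not (np.isfinite(total) and np.all(np.isfinite(grad))):
            return 1e30, np.zeros(theta0.size)
        return -total, -grad

    def stage(th_start, mask, n_iter):
        def scaled(z):
            f, g = objective_at(th_start + scales * (z * mask))
            return f, (g * scales) * mask

        res = minimize(scaled, np.zeros(theta0.size), jac=True, method="L-BFGS-B",
                       options={"maxiter": n_iter, "gtol": gtol, "ftol": 1e-14})
        return th_start + scales * (res.x * mask), float(res.fun), int(res.nit)

    mask_all = free.astype(float)
    mask_nocell = mask_all.copy()
    mask_nocell[:9] = 0.0

    f_start, _ = objective_at(theta0)
    # smooth parameters first with the cell frozen, then everything; the
    # cell moves peak positions by multiples of their widths and owns the
    # worst local minima (only local refinement is promised)
    th_a, f_a, it_a = stage(theta0, mask_nocell, maxiter // 2)
    th_b, f_b, it_b = stage(th_a, mask_all, maxiter)
    theta, f_best = min([(theta0, f_start), (th_a, f_a), (th_b, f_b)],
                        key=lambda p: p[1])
    fitted = chain.theta_to_crystal(theta[:19])
    em_out = replace(em, alpha=math.exp(theta[19]), beta=math.exp(theta[20]))
    diags = {
        "loglik_start": -f_start,
        "loglik": -f_best,
        "n_iter": it_a + it_b,
        "converged": bool(f_best < f_start or f_start <= f_b),
        "n_pairs": int(sum(p[0].size for p in all_pairs)),
    }
    return fitted, em_out, diags
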