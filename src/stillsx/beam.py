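"""Gaussian description of the illumination.

The source enters the diffraction model through three distributions in
reciprocal space: the incident wavevector ``k_in`` (spread by divergence
transverse to the beam and by bandwidth along it), the outgoing wavevector
``k_out`` (spread by bandwidth only, along the viewing direction), and
their *correlated* difference ``delta_k = k_out - k_in``.  Diffraction does
not change the wavelength, so the wavelength components of ``k_in`` and
``k_out`` are perfectly correlated and partially cancel in the difference;
the divergence component belongs to ``k_in`` alone and adds independently.

Wavenumber convention: ``nu = 1 / lambda`` (no 2 pi), units nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaussians import GaussianKernel, clip_psd

__all__ = ["BeamModel", "cov_kin", "cov_kout", "delta_k_kernel", "polarization_factor"]


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector, |v| = {n}")
    return v / n


@dataclass(frozen=True)
class BeamModel:
    """Source parameters of a (possibly pink, possibly divergent) beam.

    Parameters
    ----------
    nu0 : float
        Mean wavenumber 1/lambda in nm^-1 (e.g. lambda = 0.13 nm -> 7.69).
    bandwidth : float
        Relative standard deviation of the wavenumber distribution
        (dimensionless; FWHM/2.355 of dE/E for X-rays).
    divergence : float
        Standard deviation of the incidence angle in radians.
    w_in : (3,) array
        Mean unit beam direction (default +z).
    polarization_p : float
        Degree of polarization in [0, 1].
    pol_normal : (3,) array
        Unit normal of the polarization plane.
    flux : float
        Incident flux J0 (photons per area, arbitrary but consistent units).
    """

    nu0: float
    bandwidth: float = 0.0
    divergence: float = 0.0
    w_in: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    polarization_p: float = 0.0
    pol_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    flux: float = 1.0

    def __post_init__(self):
        if self.nu0 <= 0:
            raise ValueError("nu0 must be positive")
        if self.bandwidth < 0 or self.divergence < 0:
            raise ValueError("bandwidth and divergence must be nonnegative")
        if not 0.0 <= self.polarization_p <= 1.0:
            raise ValueError("polarization_p must lie in [0, 1]")
        object.__setattr__(self, "w_in", _unit(self.w_in, "w_in"))
        object.__setattr__(self, "pol_normal", _unit(self.pol_normal, "pol_normal"))

    @property
    def sigma_nu(self) -> float:
        """Absolute wavenumber standard deviation nu0 * bandwidth (nm^-1)."""
        return self.nu0 * self.bandwidth


def cov_kin(beam: BeamModel) -> np.ndarray:
    """Covariance of the incident wavevector.

    Isotropic divergence spreads ``k_in`` on a ring transverse to the mean
    direction; bandwidth spreads it radially along the beam.  The two are
    taken as independent:

        nu0^2 [ sigma_div^2 (I - w w^T) + bandwidth^2 w w^T ].
    """
    w = beam.w_in
    proj = np.outer(w, w)
    return beam.nu0**2 * (
        beam.divergence**2 * (np.eye(3) - proj) + beam.bandwidth**2 * proj
    )


def cov_kout(beam: BeamModel, w_out) -> np.ndarray:
    """Covariance of the outgoing wavevector toward ``w_out``.

    The outgoing distribution is not affected by divergence; it carries only
    the wavelength spread, rotated so its (rank-1) axis lies along ``w_out``.
    """
    w = _unit(w_out, "w_out")
    return beam.nu0**2 * beam.bandwidth**2 * np.outer(w, w)


def delta_k_kernel(beam: BeamModel, w_out) -> GaussianKernel:
    """Gaussian kernel of ``delta_k = k_out - k_in`` for a viewing direction.

    Both wavelength spreads are driven by the same scalar wavenumber
    deviate (diffraction preserves the wavelength), so their correlated
    difference is the rank-1 square-root factors subtracted:

        cov_bw = sigma_nu^2 (w_out - w_in)(w_out - w_in)^T,

    matching the shear geometry of the Ewald construction (the component of
    delta_k along ``w_in`` is ``nu (cos 2theta - 1)``).  The independent
    divergence contribution is added by covariance addition.  The mean is
    ``nu0 (w_out - w_in)``, which lies on the mean Ewald sphere.
    """
    w = _unit(w_out, "w_out")
    v = w - beam.w_in
    cov = beam.sigma_nu**2 * np.outer(v, v)
    if beam.divergence > 0:
        proj = np.outer(beam.w_in, beam.w_in)
        cov = cov + beam.nu0**2 * beam.divergence**2 * (np.eye(3) - proj)
    return GaussianKernel(1.0, beam.nu0 * v, clip_psd(cov))


def polarization_factor(beam: BeamModel, w_out) -> float:
    """Thomson polarization correction for scattering toward ``w_out``.

    ``C = p [1 - (w . n)^2] + (1 - p) [1 + (w . w_in)^2] / 2`` with ``p`` the
    degree of polarization and ``n`` the normal of the polarization plane.
    Normalized so that C = 1 in the forward direction.
    """
    w = _unit(w_out, "w_out")
    p = beam.polarization_p
    return float(
        p * (1.0 - (w @ beam.pol_normal) ** 2)
        + (1.0 - p) * 0.5 * (1.0 + (w @ beam.w_in) ** 2)
    )
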