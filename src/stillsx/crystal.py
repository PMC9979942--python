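"""Per-reflection reciprocal-space kernels and excited-reflection search.

A crystal is described by its reciprocal cell matrix ``R`` (peaks at
``x = R h`` for integer Miller triples ``h``), a reciprocal peak-shape
covariance (the Gaussian stand-in for the crystal's shape transform),
isotropic mosaicity (rotational disorder, broadening peaks tangentially)
and scalar strain (cell-size variation, broadening peaks radially), plus a
linear scale factor and a B factor used when predicting intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .beam import BeamModel
from .gaussians import GaussianKernel, clip_psd

__all__ = [
    "CrystalModel",
    "MillerIndex",
    "cube_shape_cov",
    "reciprocal_peak",
    "crystal_dof_count",
    "source_dof_count",
    "ewald_offset_sigma",
    "excited_reflections",
    "excited_reflections_brute_force",
]

#: Gaussian sigma matching the FWHM of the central sinc^2 lobe of a cube
#: shape transform, in units of 1/edge-length.
CUBE_SHAPE_CONSTANT = 0.3762


class MillerIndex(NamedTuple):
    h: int
    k: int
    l: int  # noqa: E741 - crystallographic convention


def cube_shape_cov(edge_length: float, c: float = CUBE_SHAPE_CONSTANT) -> np.ndarray:
    """Isotropic Gaussian approximation of a cube's shape transform.

    The diffraction of a cube of edge ``L`` has an intensity profile
    ``sinc^2(pi L q)`` along each axis; the default constant matches the
    full width at half maximum of its central lobe to that of a Gaussian,
    giving ``sigma = c / L`` with ``c ~= 0.376``.  The constant is exposed
    because the Gaussian stand-in for a sinc^2 is a modelling choice, not a
    unique value.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    return (c / edge_length) ** 2 * np.eye(3)


@dataclass(frozen=True)
class CrystalModel:
    """Reciprocal cell, peak broadening and intensity-scaling parameters.

    Parameters
    ----------
    R : (3, 3) array
        Reciprocal unit-cell matrix in nm^-1 per Miller-index unit; rows are
        the reciprocal basis vectors a*, b*, c*.
    shape_cov : (3, 3) array
        PSD covariance of the intrinsic reciprocal peak shape (nm^-2).
    mosaicity : float
        Standard deviation of isotropic rotational disorder (radians).
    strain : float
        Standard deviation of relative unit-cell size variation.
    scale_a : float
        Linear intensity scale of this crystal.
    b_factor : float
        Gaussian intensity-decay parameter B (nm^2): intensities are damped
        by ``exp(-B |x|^2 / 2)``.
    """

    R: np.ndarray
    shape_cov: np.ndarray = field(default_factory=lambda: 1e-4 * np.eye(3))
    mosaicity: float = 0.0
    strain: float = 0.0
    scale_a: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(R)) < 1e-300:
            raise ValueError("reciprocal cell matrix R is singular")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "shape_cov", clip_psd(np.asarray(self.shape_cov, float)))
        if self.mosaicity < 0 or self.strain < 0:
            raise ValueError("mosaicity and strain must be nonnegative")
        if self.scale_a <= 0:
            raise ValueError("scale_a must be positive")

    def peak_position(self, hkl) -> np.ndarray:
        """Reciprocal-space position x = R h of a reflection."""
        return self.R @ np.asarray(hkl, dtype=float).reshape(3)


def peak_cov_at(crystal: CrystalModel, x: np.ndarray) -> np.ndarray:
    """Peak covariance at reciprocal position ``x`` (not necessarily R h)."""
    x = np.asarray(x, dtype=float).reshape(3)
    xx = np.outer(x, x)
    q2 = float(x @ x)
    cov = (
        crystal.shape_cov
        + crystal.mosaicity**2 * (q2 * np.eye(3) - xx)
        + crystal.strain**2 * xx
    )
    return clip_psd(cov)


def reciprocal_peak(crystal: CrystalModel, hkl) -> GaussianKernel:
    """Gaussian kernel of one reciprocal-lattice peak.

    Mean ``x = R h``; covariance is the sum of the shape transform, the
    small-angle second moment of isotropic rotational disorder
    ``sigma_m^2 (|x|^2 I - x x^T)`` (tangential only) and radial strain
    ``sigma_s^2 x x^T``.  Both disorder terms vanish at the origin.
    """
    x = crystal.peak_position(hkl)
    return GaussianKernel(1.0, x, peak_cov_at(crystal, x))


def crystal_dof_count(crystal: CrystalModel, include_scaling: bool = False) -> int:
    """Independent scalar parameters of the crystal's diffraction kernel.

    Nine for the unit cell, six for the symmetric shape covariance and one
    each for mosaicity and strain = 17; scale and B add two more when
    ``include_scaling`` is on.
    """
    n = crystal.R.size + 6 + 1 + 1
    if include_scaling:
        n += 2
    return n


def source_dof_count() -> int:
    """Parameters of one source kernel: 3 for the mean direction plus 6 for
    a possibly correlated angle/wavelength covariance."""
    return 3 + 6


def ewald_offset_sigma(
    crystal: CrystalModel, beam: BeamModel, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance to the Ewald sphere and the matching Gaussian width.

    For reciprocal positions ``x`` (shape (N, 3) or (3,)) returns
    ``(delta, sigma, w_c)`` where ``delta = nu0 - |nu0 w_in + x|`` is the
    signed distance from the peak to the mean Ewald sphere, ``sigma`` is
    the standard deviation of the combined delta-k + peak distribution
    projected on the optimal outgoing direction ``w_c`` (the direction of
    closest sphere approach), and ``|delta| / sigma`` is the Mahalanobis
    excitation distance used for significance tests.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k = beam.nu0 * beam.w_in + x  # outgoing wavevector candidates
    norm = np.linalg.norm(k, axis=1)
    w_c = k / norm[:, None]
    delta = beam.nu0 - norm
    c = w_c @ beam.w_in
    var_dk = beam.sigma_nu**2 * (1.0 - c) ** 2 + (beam.nu0 * beam.divergence) ** 2 * (
        1.0 - c**2
    )
    wx = np.einsum("ni,ni->n", w_c, x)
    q2 = np.einsum("ni,ni->n", x, x)
    var_pk = (
        np.einsum("ni,ij,nj->n", w_c, crystal.shape_cov, w_c)
        + crystal.mosaicity**2 * np.clip(q2 - wx**2, 0.0, None)
        + crystal.strain**2 * wx**2
    )
    sigma = np.sqrt(var_dk + var_pk)
    return delta, sigma, w_c


def _hkl_box(crystal: CrystalModel, q_max: float) -> np.ndarray:
    """All integer hkl whose peak could lie within |x| <= q_max."""
    Rinv = np.linalg.inv(crystal.R)
    lim = np.ceil(np.linalg.norm(Rinv, axis=1) * q_max).astype(int)
    hs = [np.arange(-n, n + 1) for n in lim]
    grid = np.stack(np.meshgrid(*hs, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def excited_reflections_brute_force(
    crystal: CrystalModel,
    beam: BeamModel,
    sigma_cutoff: float,
    d_min: float,
    include_origin: bool = False,
) -> set[MillerIndex]:
    """Exhaustive enumeration over the resolution sphere.

    A reflection is excited when its Mahalanobis distance to the Ewald
    sphere, ``|delta| / sigma``, is below ``sigma_cutoff`` and it lies
    within the resolution limit ``|x| <= 1 / d_min``.
    """
    if sigma_cutoff <= 0 or d_min <= 0:
        raise ValueError("sigma_cutoff and d_min must be positive")
    q_max = 1.0 / d_min
    grid = _hkl_box(crystal, q_max)
    x = grid @ crystal.R.T
    q = np.linalg.norm(x, axis=1)
    sel = q <= q_max
    grid, x = grid[sel], x[sel]
    delta, sigma, _ = ewald_offset_sigma(crystal, beam, x)
    hit = np.abs(delta) <= sigma_cutoff * sigma
    out = {MillerIndex(*map(int, h)) for h in grid[hit]}
    if not include_origin:
        out.discard(MillerIndex(0, 0, 0))
    return out


def excited_reflections(
    crystal: CrystalModel,
    beam: BeamModel,
    sigma_cutoff: float,
    d_min: float,
    include_origin: bool = False,
    n_seeds: int = 256,
) -> set[MillerIndex]:
    """Region-growing search for excited reflections.

    Traverses the integer lattice with 26-neighbour connectivity starting
    from seeds on the resolution-limited Ewald cap, expanding through every
    cell whose unit cube could intersect the diffraction condition (the
    per-cell test adds the cell circumradius to the significance band, so
    the traversal is an acceleration of -- and set-equal to -- the brute
    force enumeration).  The final membership test is identical to the
    brute-force criterion.
    """
    if sigma_cutoff <= 0 or d_min <= 0:
        raise ValueError("sigma_cutoff and d_min must be positive")
    q_max = 1.0 / d_min
    R = crystal.R
    # circumradius of one hkl unit cell in reciprocal space
    corners = np.array(
        [[i, j, k] for i in (-0.5, 0.5) for j in (-0.5, 0.5) for k in (-0.5, 0.5)]
    )
    rho = float(np.max(np.linalg.norm(corners @ R.T, axis=1)))

    Rinv = np.linalg.inv(R)
    # seed cells: quasi-uniform directions on the Ewald sphere, clipped to
    # the resolution cap (golden-angle spiral)
    i = np.arange(n_seeds)
    z = 1.0 - 2.0 * (i + 0.5) / n_seeds
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    xs = beam.nu0 * (dirs - beam.w_in)
    xs = xs[np.linalg.norm(xs, axis=1) <= q_max + rho]
    seeds = {tuple(np.rint(Rinv @ x).astype(int)) for x in xs}
    seeds.add((0, 0, 0))

    offsets = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )

    def cell_may_intersect(batch: np.ndarray) -> np.ndarray:
        x = batch @ R.T
        q = np.linalg.norm(x, axis=1)
        delta, sigma, _ = ewald_offset_sigma(crystal, beam, x)
        near_band = np.abs(delta) <= sigma_cutoff * sigma + 2.0 * rho
        in_res = q <= q_max + rho
        return near_band & in_res

    def cell_excited(batch: np.ndarray) -> np.ndarray:
        x = batch @ R.T
        q = np.linalg.norm(x, axis=1)
        delta, sigma, _ = ewald_offset_sigma(crystal, beam, x)
        return (np.abs(delta) <= sigma_cutoff * sigma) & (q <= q_max)

    visited: set[tuple[int, int, int]] = set(seeds)
    frontier = np.array(sorted(seeds), dtype=int)
    excited: set[MillerIndex] = set()
    while frontier.size:
        grow = cell_may_intersect(frontier)
        hits = cell_excited(frontier)
        for h in frontier[hits]:
            excited.add(MillerIndex(*map(int, h)))
        growing = frontier[grow]
        if growing.size == 0:
            break
        neigh = (growing[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        fresh = [tuple(map(int, n)) for n in neigh]
        nxt = [n for n in dict.fromkeys(fresh) if n not in visited]
        visited.update(nxt)
        frontier = np.array(nxt, dtype=int).reshape(-1, 3)
    if not include_origin:
        excited.discard(MillerIndex(0, 0, 0))
    return excited
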