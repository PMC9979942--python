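"""Synthetic indexed-stills data with the statistical structure the model
assumes.

The generator emulates a serial-crystallography experiment at the level of
integrated intensities: uniformly random crystal orientations, Wilson-like
(acentric exponential) true intensities, per-crystal log-normal scale and
B-factor variation, Gaussian measurement noise from the two-parameter
error model, and a stated fraction of heavy-tailed (Cauchy) outliers.
Negative noisy intensities are retained -- they carry information about
reflections far from the diffraction condition.  Toy pixel images come
from the full pattern-prediction path plus flat background and noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .beam import BeamModel
from .crystal import CrystalModel, excited_reflections_brute_force
from .detector import DetectorGeometry, Panel
from .merging import asu_index
from . import chain

__all__ = ["SimulationConfig", "simulate_crystals", "simulate_observations",
           "generate_toy_image", "default_beam", "default_detector"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic stills experiment.

    Defaults describe a small, well-ordered protein microcrystal data set
    at an XFEL-like source: 10 nm cubic cell, 0.13 nm photons with 0.1%
    rms bandwidth (SASE-like), mosaicity 1 mrad, strain 1e-3, intensity
    observations to 0.8 nm resolution with a generous excitation cutoff
    (overprediction), Poisson-scale counting noise plus 5% systematic
    error and a 1/16 Cauchy outlier fraction.
    """

    n_crystals: int = 200
    cell_edge: float = 10.0  # nm, cubic base cell
    cell_jitter: float = 5e-4  # relative sd of reciprocal-cell entries
    intensity_mean: float = 1000.0  # Wilson (exponential) mean of |F|^2
    scale_sigma: float = 0.2  # log-normal sd of per-crystal scale
    b_factor_sigma: float = 0.02  # sd of per-crystal B (nm^2)
    mosaicity: float = 1e-3  # rad
    strain: float = 1e-3
    shape_sigma: float = 2e-3  # nm^-1, isotropic reciprocal peak width
    wavelength: float = 0.13  # nm
    bandwidth: float = 1e-3
    divergence: float = 1e-4  # rad
    flux: float = 1.0
    d_min: float = 0.8  # nm
    sigma_cutoff: float = 3.0
    alpha: float = 1.0
    beta: float = 2.5e-3  # (5% systematic error)^2
    sigma_counting_floor: float = 2.0  # counts, background-subtraction noise
    counts_per_intensity: float = 1.0  # counting-variance scale
    outlier_fraction: float = 1.0 / 16.0
    outlier_gamma: float | None = None  # default: intensity_mean / 2
    seed: int = 0

    def __post_init__(self):
        for name in ("cell_jitter", "intensity_mean", "scale_sigma", "mosaicity",
                     "strain", "shape_sigma", "bandwidth", "divergence", "alpha",
                     "beta", "outlier_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def default_beam(cfg: SimulationConfig) -> BeamModel:
    return BeamModel(
        nu0=1.0 / cfg.wavelength,
        bandwidth=cfg.bandwidth,
        divergence=cfg.divergence,
        polarization_p=0.0,
        flux=cfg.flux,
    )


def default_detector(n_px: int = 64, pixel_m: float = 200e-6, distance_m: float = 0.08,
                     gain: float = 1.0) -> DetectorGeometry:
    """A single square on-axis panel centred on the beam."""
    D = np.array([[pixel_m, 0.0], [0.0, pixel_m], [0.0, 0.0]])
    o = np.array([-n_px / 2 * pixel_m, -n_px / 2 * pixel_m, distance_m])
    return DetectorGeometry((Panel(D=D, origin_o=o, n_fs=n_px, n_ss=n_px,
                                   gain_g=gain, name="panel0"),))


def simulate_crystals(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Uniformly oriented copies of the base cell with small metric jitter."""
    rng = rng or np.random.default_rng(cfg.seed)
    a_star = 1.0 / cfg.cell_edge
    base = a_star * np.eye(3)
    crystals = []
    rots = Rotation.random(cfg.n_crystals, random_state=rng).as_matrix()
    for i in range(cfg.n_crystals):
        jitter = 1.0 + cfg.cell_jitter * rng.standard_normal((3, 3))
        R = rots[i] @ (base * jitter)
        scale = float(np.exp(cfg.scale_sigma * rng.standard_normal()))
        b = abs(cfg.b_factor_sigma * rng.standard_normal())
        crystals.append(
            CrystalModel(
                R=R,
                shape_cov=cfg.shape_sigma**2 * np.eye(3),
                mosaicity=cfg.mosaicity,
                strain=cfg.strain,
                scale_a=scale,
                b_factor=b,
            )
        )
    return crystals


def true_intensities(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Wilson-like exponential intensities for every unique reflection in
    the resolution sphere of the base cell."""
    a_star = 1.0 / cfg.cell_edge
    n = int(np.ceil(1.0 / (cfg.d_min * a_star)))
    hs = np.arange(-n, n + 1)
    grid = np.stack(np.meshgrid(hs, hs, hs, indexing="ij"), axis=-1).reshape(-1, 3)
    q = np.linalg.norm(grid * a_star, axis=1)
    grid = grid[(q <= 1.0 / cfg.d_min) & (q > 0)]
    asu = np.unique(asu_index(grid), axis=0)
    vals = rng.exponential(cfg.intensity_mean, size=len(asu))
    return {tuple(int(i) for i in h): float(v) for h, v in zip(asu, vals)}


def simulate_observations(
    crystals,
    beam: BeamModel,
    truth: dict,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Integrated-intensity observations for every excited reflection.

    Intensity = predicted (partiality-corrected, scaled) intensity plus
    Gaussian noise of error-model variance; a fraction ``outlier_fraction``
    is replaced by Cauchy draws.  Counting sigmas follow a square-root law
    with an additive floor, mimicking integration over background.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    gamma = cfg.outlier_gamma if cfg.outlier_gamma is not None else cfg.intensity_mean / 2
    rows = []
    for cid, crystal in enumerate(crystals):
        hkls = sorted(excited_reflections_brute_force(
            crystal, beam, cfg.sigma_cutoff, cfg.d_min))
        if not hkls:
            continue
        hkl_arr = np.array(hkls, dtype=float)
        t = chain.reflection_terms(
            crystal.R, crystal.shape_cov, crystal.mosaicity, crystal.strain,
            crystal.scale_a, crystal.b_factor, hkl_arr, beam, gain=1.0,
        )
        asu = asu_index(hkl_arr.astype(int))
        I_true = np.array([truth.get(tuple(int(i) for i in h), 0.0) for h in asu])
        pred = np.asarray(t.coef) * I_true
        sigma_c = np.sqrt(
            cfg.sigma_counting_floor**2
            + cfg.counts_per_intensity * np.clip(pred, 0.0, None)
        )
        var = cfg.alpha * sigma_c**2 + cfg.beta * pred**2
        I_noisy = pred + rng.normal(0.0, np.sqrt(var))
        is_out = rng.random(len(hkls)) < cfg.outlier_fraction
        n_out = int(is_out.sum())
        if n_out:
            I_noisy[is_out] = gamma * rng.standard_cauchy(n_out)
        for j, hkl in enumerate(hkls):
            rows.append(
                (cid, hkl[0], hkl[1], hkl[2], I_noisy[j], sigma_c[j], "panel0", 0.0, 0.0)
            )
    return pd.DataFrame(
        rows, columns=["crystal_id", "h", "k", "l", "I", "sigma", "panel", "fs", "ss"]
    )


def generate_toy_image(
    crystal: CrystalModel,
    beam: BeamModel,
    detector: DetectorGeometry,
    truth: dict,
    cfg: SimulationConfig,
    background_level: float = 0.0,
    noise: bool = False,
    rng: np.random.Generator | None = None,
    sigma_cutoff: float = 4.0,
    oversample: int = 1,
):
    """Predicted still image plus flat background and optional noise.

    Returns ``(images, backgrounds)`` dicts keyed by panel name.
    """
    from .pattern import predict_pattern

    rng = rng or np.random.default_rng(cfg.seed + 2)
    backgrounds = {
        p.name: np.full((p.n_fs, p.n_ss), float(background_level)) for p in detector
    }
    images = predict_pattern(
        crystal, beam, detector, truth, background=backgrounds,
        sigma_cutoff=sigma_cutoff, d_min=cfg.d_min, oversample=oversample,
    )
    if noise:
        for name, img in images.items():
            images[name] = img + rng.normal(
                0.0, np.sqrt(cfg.alpha * np.clip(img, 0.0, None) + 1.0)
            )
    return images, backgrounds
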