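"""Rigid-panel detector geometry.

A panel maps pixel coordinates ``(fs, ss)`` (fast scan / slow scan, defined
by memory order) to lab space through a 3x2 basis matrix ``D`` and a corner
offset ``o``: the lab position of a pixel sample is ``o + D (fs, ss)``.
The interaction point is the lab origin; pixel centers sit at half-integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaussians import clip_psd

__all__ = [
    "Panel",
    "DetectorGeometry",
    "pixel_direction",
    "direction_derivatives",
    "solid_angle",
    "solid_angle_exact",
    "smoothing_covariance",
]


@dataclass(frozen=True)
class Panel:
    """One rigid detector panel.

    Parameters
    ----------
    D : (3, 2) array
        Lab displacement per (fs, ss) pixel step, in metres per pixel.
    origin_o : (3,) array
        Lab position of the (0, 0) pixel corner (metres).
    n_fs, n_ss : int
        Pixel counts along the two axes.
    gain_g : float
        Detector counts per wavenumber per photon (integrating detector:
        the reading is proportional to deposited photon energy).
    name : str
    """

    D: np.ndarray
    origin_o: np.ndarray
    n_fs: int
    n_ss: int
    gain_g: float = 1.0
    name: str = "panel0"

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float).reshape(3, 2)
        if np.linalg.matrix_rank(D) < 2:
            raise ValueError(f"panel {self.name}: columns of D must be independent")
        object.__setattr__(self, "D", D)
        object.__setattr__(
            self, "origin_o", np.asarray(self.origin_o, dtype=float).reshape(3)
        )
        if self.n_fs < 1 or self.n_ss < 1:
            raise ValueError("pixel counts must be >= 1")
        if self.gain_g <= 0:
            raise ValueError("gain must be positive")

    def lab_position(self, fs: float, ss: float) -> np.ndarray:
        """Lab position of pixel sample point (corner-referenced coords)."""
        return self.origin_o + self.D @ np.array([fs, ss], dtype=float)


@dataclass(frozen=True)
class DetectorGeometry:
    panels: tuple[Panel, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "panels", tuple(self.panels))
        names = [p.name for p in self.panels]
        if len(set(names)) != len(names):
            raise ValueError("panel names must be unique")

    def __iter__(self):
        return iter(self.panels)

    def panel(self, name: str) -> Panel:
        for p in self.panels:
            if p.name == name:
                return p
        raise KeyError(f"no panel named {name!r}")


def pixel_direction(panel: Panel, fs: float, ss: float) -> np.ndarray:
    """Unit direction from the interaction point to the pixel *center*.

    ``fs``/``ss`` are 0-based pixel indices; the sampled lab point is
    ``o + D (fs + 1/2, ss + 1/2)``.
    """
    r = panel.lab_position(fs + 0.5, ss + 0.5)
    n = np.linalg.norm(r)
    if n < 1e-12:
        raise ValueError("pixel coincides with the interaction point")
    return r / n


def direction_derivatives(panel: Panel, fs: float, ss: float) -> np.ndarray:
    """(3, 2) derivatives of the unit direction w.r.t. (fs, ss).

    For ``w = r / |r|``: ``dw = (I - w w^T) dr / |r|``.
    """
    r = panel.lab_position(fs + 0.5, ss + 0.5)
    n = np.linalg.norm(r)
    w = r / n
    return (panel.D - np.outer(w, w @ panel.D)) / n


def solid_angle(panel: Panel, fs: float, ss: float) -> float:
    """Solid angle of one pixel: cross product of the projected pixel sides.

    The pixel sides projected onto the unit sphere are the direction
    derivatives; the subtended area is the norm of their cross product.
    """
    J = direction_derivatives(panel, fs, ss)
    return float(np.linalg.norm(np.cross(J[:, 0], J[:, 1])))


def solid_angle_exact(panel: Panel, fs: float, ss: float) -> float:
    """Exact solid angle of the pixel quadrilateral (Van Oosterom-Strackee).

    Splits the pixel into two spherical triangles; used as the independent
    oracle for :func:`solid_angle`.
    """

    def tri(a, b, c):
        na, nb, nc = (np.linalg.norm(v) for v in (a, b, c))
        num = float(a @ np.cross(b, c))
        den = na * nb * nc + (a @ b) * nc + (a @ c) * nb + (b @ c) * na
        return 2.0 * abs(np.arctan2(num, den))

    p00 = panel.lab_position(fs, ss)
    p10 = panel.lab_position(fs + 1.0, ss)
    p11 = panel.lab_position(fs + 1.0, ss + 1.0)
    p01 = panel.lab_position(fs, ss + 1.0)
    return tri(p00, p10, p11) + tri(p00, p11, p01)


def smoothing_covariance(
    panel: Panel, fs: float, ss: float, oversample: int = 1
) -> np.ndarray:
    """Direction-space covariance of the analytic detector point spread.

    Sampling a sharply peaked flux density only at pixel centers would
    alias; convolving the prediction with a Gaussian whose standard
    deviation is half a pixel extent per axis smooths it enough for
    center-sampling while conserving total flux.  With oversampling factor
    ``s`` the extent (and hence sigma) shrinks by ``1/s``:

        Sigma_+ = (1 / (2 s))^2 (d_fs d_fs^T + d_ss d_ss^T),

    where ``d_fs``/``d_ss`` are the direction derivatives of the pixel.
    Rank <= 2 (the spread is tangent to the sphere).
    """
    if oversample < 1 or int(oversample) != oversample:
        raise ValueError("oversample must be a positive integer")
    J = direction_derivatives(panel, fs, ss)
    sig = 0.5 / oversample
    return clip_psd(sig**2 * (np.outer(J[:, 0], J[:, 0]) + np.outer(J[:, 1], J[:, 1])))
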