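"""Predict a still diffraction pattern pixel by pixel.

Builds a randomly oriented 10 nm cubic microcrystal, a slightly pink
XFEL-like beam, a small on-axis detector, and Wilson-distributed true
intensities, then evaluates the closed-form expected reading of every
pixel touched by an excited reflection.
"""

import numpy as np

from stillsx import excited_reflections, predict_pattern
from stillsx.simulate import (
    SimulationConfig,
    default_beam,
    default_detector,
    simulate_crystals,
    true_intensities,
)

cfg = SimulationConfig(n_crystals=1, seed=5, bandwidth=2e-3)
rng = np.random.default_rng(cfg.seed)
beam = default_beam(cfg)
crystal = simulate_crystals(cfg, rng)[0]
truth = true_intensities(cfg, rng)
detector = default_detector(n_px=96, distance_m=0.05)

hkls = excited_reflections(crystal, beam, sigma_cutoff=4.0, d_min=cfg.d_min)
images = predict_pattern(crystal, beam, detector, truth,
                         sigma_cutoff=4.0, d_min=cfg.d_min)
img = images["panel0"]

print(f"excited reflections: {len(hkls)}")
print(f"pixels with signal:  {(img > 1e-9).sum()} of {img.size}")
print(f"total reading:       {img.sum():.1f} counts")
fs, ss = (int(i) for i in np.unravel_index(img.argmax(), img.shape))
print(f"brightest pixel:     {img.max():.1f} counts at (fs={fs}, ss={ss})")
# The totals are detector counts: gain * wavenumber * photon flux * solid
# angle summed over the reflections whose reciprocal peaks intersect the
# (bandwidth-broadened) Ewald sphere for this orientation.
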