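"""Partiality of one reflection as the crystal rotates off the condition.

Places a reflection exactly on the Ewald sphere, then rotates the crystal
in small steps and prints the closed-form partiality -- the ratio of the
integrated intensity to its maximum over orientations -- together with the
signed distance of the peak from the sphere.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from stillsx import BeamModel, CrystalModel, predict_reflection

crystal0 = CrystalModel(R=0.1 * np.eye(3), shape_cov=(2e-3) ** 2 * np.eye(3),
                        mosaicity=1e-3, strain=1e-3)
hkl = (3, 1, 5)
x = crystal0.peak_position(hkl)

# orient the beam so the reflection starts fully recorded
nu0 = 1.0 / 0.13
u = x / np.linalg.norm(x)
t = np.cross(u, [1.0, 0.0, 0.0]); t /= np.linalg.norm(t)
c = -np.linalg.norm(x) / (2 * nu0)
beam = BeamModel(nu0=nu0, w_in=c * u + np.sqrt(1 - c**2) * t,
                 bandwidth=1e-3, divergence=1e-4)

print(f"reflection {hkl}, |x| = {np.linalg.norm(x):.3f} nm^-1 "
      f"(d = {1 / np.linalg.norm(x):.2f} nm)")
print(f"{'rotation (mrad)':>16} {'delta (nm^-1)':>14} {'partiality':>11}")
axis = np.cross(u, beam.w_in); axis /= np.linalg.norm(axis)
for mrad in (0.0, 0.2, 0.5, 1.0, 2.0, 4.0):
    rot = Rotation.from_rotvec(1e-3 * mrad * axis).as_matrix()
    crystal = CrystalModel(R=rot @ crystal0.R, shape_cov=crystal0.shape_cov,
                           mosaicity=crystal0.mosaicity, strain=crystal0.strain)
    p = predict_reflection(crystal, beam, hkl, refine=False)
    delta = nu0 - np.linalg.norm(nu0 * beam.w_in + crystal.peak_position(hkl))
    print(f"{mrad:16.1f} {delta:14.5f} {p.partiality:11.4f}")
# The partiality decays as a Gaussian in the peak's distance from the
# Ewald sphere, with width set by bandwidth, divergence, peak shape,
# mosaicity and strain combined.
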