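import numpy as np
import pytest

from stillsx.beam import BeamModel
from stillsx.crystal import CrystalModel
from stillsx.gaussians import GaussianKernel


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_psd(rng, scale=1.0, dim=3):
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T + 0.1 * np.eye(dim))


def random_kernel(rng, weight_scale=1.0, mean_scale=1.0, cov_scale=1.0):
    return GaussianKernel(
        weight=float(rng.uniform(0.1, 1.0)) * weight_scale,
        mean=mean_scale * rng.standard_normal(3),
        cov=random_psd(rng, cov_scale),
    )


@pytest.fixture
def xray_beam():
    """0.13 nm photons, 0.1% rms bandwidth, small divergence."""
    return BeamModel(nu0=1.0 / 0.13, bandwidth=1e-3, divergence=1e-4)


@pytest.fixture
def mono_beam():
    return BeamModel(nu0=1.0 / 0.13)


@pytest.fixture
def cubic_crystal():
    """10 nm cubic cell with realistic micro-crystal broadening."""
    return CrystalModel(
        R=0.1 * np.eye(3),
        shape_cov=(2e-3) ** 2 * np.eye(3),
        mosaicity=1e-3,
        strain=1e-3,
    )
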