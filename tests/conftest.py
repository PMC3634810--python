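import numpy as np
import pytest

import somafinder as sf


@pytest.fixture(scope="session")
def params():
    return sf.PhysicalParams()


@pytest.fixture(scope="session")
def fan162():
    return sf.ray_directions(2)


def digitized_ball(radius_um, spacing=(0.35, 0.35, 1.0), margin_um=3.0):
    """Boolean ball mask on an odd-sized grid with its exact center voxel."""
    sp = np.asarray(spacing, dtype=float)
    half = radius_um + margin_um
    shape = tuple(int(np.ceil(2 * half / s)) | 1 for s in sp)
    center = (np.asarray(shape) // 2) * sp
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, sp, center)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(gx ** 2 + gy ** 2 + gz ** 2) <= radius_um, center


@pytest.fixture(scope="session")
def solid_soma_phantom():
    """One solid 24 um soma, no neurites, no noise."""
    spec = sf.PhantomSpec(shape_um=(50, 50, 50), n_somas=1, soma_diam_range=(24, 24),
                          hollow_fraction=0.0, n_neurites=0, noise_sigma=0,
                          placement="uniform", min_separation_um=1,
                          ellipticity=0.0, seed=11)
    return sf.generate_phantom(spec)


@pytest.fixture(scope="session")
def hollow_soma_phantom():
    """One hollow 16 um soma, no neurites, no noise."""
    spec = sf.PhantomSpec(shape_um=(40, 40, 40), n_somas=1, soma_diam_range=(16, 16),
                          hollow_fraction=1.0, n_neurites=0, noise_sigma=0,
                          placement="uniform", min_separation_um=1,
                          ellipticity=0.0, seed=12)
    return sf.generate_phantom(spec)
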