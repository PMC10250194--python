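import numpy as np
import pytest

import flexrec as fr
from flexrec.model import default_mesh


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_spec():
    return fr.ToyMoleculeSpec()


@pytest.fixture(scope="session")
def toy_volume(toy_spec):
    return fr.make_toy_volume(toy_spec)


@pytest.fixture(scope="session")
def toy_mesh(toy_volume):
    """Regular 8-voxel mesh over the toy molecule, with density weights."""
    return default_mesh(toy_volume, element_size_A=24.0)


@pytest.fixture(scope="session")
def small_dataset(toy_spec):
    """A small simulated hinge dataset shared by cheap tests."""
    return fr.generate_dataset(toy_spec, m=40, snr=0.5, seed=7)


def gaussian_volume(n, blobs, voxel=1.0):
    """Sum of isotropic Gaussians ((cx, cy, cz), sigma, amp) on an n-grid."""
    zz, yy, xx = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    data = np.zeros((n, n, n))
    for (cx, cy, cz), s, a in blobs:
        data += a * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) / (2 * s * s)))
    return fr.CanonicalVolume(data, voxel)
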