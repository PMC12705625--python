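"""Shared fixtures: phantoms and their derived products, built once per session."""

import numpy as np
import pytest

from picsparcel import synthetic_phantom as sp
from picsparcel import tensor_model as tm
from picsparcel.io_formats import Affine, LabelVolume
from picsparcel.pipeline import parcellate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default 5-bundle phantom, 30 directions."""
    spec = sp.default_spec(n_directions=30, seed=0)
    dwi, truth = sp.make_phantom(spec)
    return spec, dwi, truth


@pytest.fixture(scope="session")
def phantom_fit(default_phantom):
    """Tensor fit, FA map, and principal-direction field for the default phantom."""
    _, dwi, _ = default_phantom
    tensors = tm.fit_tensor(dwi)
    fa = tm.compute_fa(tensors)
    dirfield = tm.principal_direction(tensors)
    return tensors, fa, dirfield


@pytest.fixture(scope="session")
def phantom_parcellation(default_phantom):
    """Full parcellation of the default noiseless phantom (probabilistic
    tracking per territory, parcels, skeletons, ordering)."""
    spec, _, _ = default_phantom
    return parcellate_phantom(spec, n_samples=500, track_seed=0)


@pytest.fixture()
def unit_affine():
    """1 mm isotropic affine with the origin at voxel (0,0,0)."""
    return Affine(np.eye(4))


def straight_field(shape=(11, 11, 11), axis=2):
    """Uniform unit direction field along one axis."""
    f = np.zeros(shape + (3,))
    f[..., axis] = 1.0
    return f


@pytest.fixture()
def uniform_z_setup(unit_affine):
    """Constant +z field with FA 0.8 everywhere and a central seed voxel."""
    from picsparcel.tensor_model import FAMap

    shape = (11, 11, 11)
    field = straight_field(shape)
    fa = FAMap(np.full(shape, 0.8), unit_affine)
    seeds = np.zeros(shape, dtype=np.int32)
    seeds[5, 5, 5] = 1
    return field, fa, LabelVolume(seeds, unit_affine, {1: "seed"})
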