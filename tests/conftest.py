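import numpy as np
import pytest

from tractprox.phantom import GroundTruth, PhantomConfig, generate_phantom
from tractprox.tensor import TensorField, fa


def make_uniform_field(shape=(21, 21, 21), voxel=2.0, direction=(1.0, 0.0, 0.0),
                       lambdas=(1.7e-3, 0.3e-3, 0.3e-3)) -> TensorField:
    """Homogeneous prolate tensor field centred on the world origin."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    l1, l2, l3 = lambdas
    tensor = l2 * np.eye(3) + (l1 - l2) * np.outer(d, d)
    w, v = np.linalg.eigh(tensor)
    w, v = w[::-1], v[:, ::-1]
    grid = tuple(shape)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = -voxel * (np.array(shape) - 1) / 2.0
    ones = np.ones(grid)
    return TensorField(
        eigenvalues=np.broadcast_to(w, grid + (3,)).copy(),
        eigenvectors=np.broadcast_to(v, grid + (3, 3)).copy(),
        fa=fa(w) * ones,
        valid_mask=ones.astype(bool),
        affine=affine,
        tensors=np.broadcast_to(tensor, grid + (3, 3)).copy(),
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomConfig(snr=None, rng_seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomConfig(snr=20.0, rng_seed=7))


@pytest.fixture(scope="session")
def fitted_noiseless(noiseless_phantom):
    from tractprox.tensor import fit_tensors

    dwi, _, _ = noiseless_phantom
    return fit_tensors(dwi)


@pytest.fixture(scope="session")
def fitted_noisy(noisy_phantom):
    from tractprox.tensor import fit_tensors

    dwi, _, _ = noisy_phantom
    return fit_tensors(dwi)
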