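import numpy as np
import pytest

from petradiomics.petio import PETVolume, ROIMask
from petradiomics.radiomics.discretize import DiscretizedROI
from petradiomics.synthcohort import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """A small textured ellipsoid phantom shared across tests."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing=(2.0, 2.0, 2.0),
        ellipsoid_radii=(12.0, 10.0, 9.0),
        base_suv=5.0,
        texture_corr_mm=5.0,
        texture_amplitude=1.2,
        noise_sd=0.15,
        seed=1,
    )
    return generate_phantom(spec)


def random_levels(seed: int, max_edge: int = 5, ng_max: int = 4) -> np.ndarray:
    """Random small gray-level grid (0 = out of mask) with >= 2 levels present."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_edge + 1, size=3))
    ng = int(rng.integers(2, ng_max + 1))
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.8
    levels = np.where(mask, levels, 0)
    # guarantee at least two in-mask voxels with two distinct levels
    levels.flat[0] = 1
    levels.flat[1] = 2
    return levels.astype(np.int64)


def roi_from_levels(levels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> DiscretizedROI:
    mask = levels > 0
    return DiscretizedROI(
        levels=levels, mask=mask, spacing=tuple(spacing),
        ng=int(levels.max()), method="fbs", param=1.0,
    )


def volume_from_array(arr, spacing=(1.0, 1.0, 1.0)) -> PETVolume:
    return PETVolume(np.asarray(arr, dtype=float), tuple(spacing))


def mask_from_array(arr, spacing=(1.0, 1.0, 1.0)) -> ROIMask:
    return ROIMask(np.asarray(arr) > 0, tuple(spacing))
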