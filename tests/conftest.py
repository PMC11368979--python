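import numpy as np
import pytest

from theradose.kinetics import KineticParams
from theradose.phantom import LinkageSpec, OrganSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_config(noise_cv=0.02, gradient_amplitude=0.3,
                 linkage=None, grid=32, radius_frac=0.75):
    """A single-organ phantom config small enough for unit tests."""
    half = grid / 2.0
    organ = OrganSpec(
        organ_id=1,
        center=((grid - 1) / 2.0,) * 3,
        radii=(radius_frac * half,) * 3,
    )
    return PhantomConfig(
        grid_shape=(grid,) * 3,
        voxel_size_mm=(4.0, 4.0, 4.0),
        organs=(organ,),
        gradient_amplitude=gradient_amplitude,
        noise_cv=noise_cv,
        linkage=linkage or LinkageSpec.homogeneous(),
    )


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_config(), seed=7)


def random_params(rng, n=1):
    """Positive, clearing kinetic parameter draws for oracle comparisons."""
    draws = []
    for _ in range(n):
        k1 = rng.uniform(0.05, 1.0)
        k2 = rng.uniform(0.05, 0.6)
        k3 = rng.uniform(0.0, 0.3)
        k4 = rng.uniform(0.0, 0.05)
        vb = rng.uniform(0.0, 0.3)
        draws.append(KineticParams(k1, k2, k3, k4, vb))
    return draws if n > 1 else draws[0]
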