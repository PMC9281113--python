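import numpy as np
import pytest

from plaquevol.phantom import PhantomSpec, PlaqueTruth, generate_phantom

# Small-grid phantom used by the unit tests: 6 x 6 mm field, 8 slices of
# 0.5 mm, same voxel size as the full protocol so plaque/voxel geometry is
# representative while everything runs in milliseconds.
SMALL_KW = dict(
    matrix_rows=96,
    matrix_cols=96,
    n_slices=8,
    spacing=(0.0625, 0.0625, 0.5),
)

# three disjoint plaques, well inside the brain ellipse, > 1.2 mm apart
SMALL_PLAQUES = [
    PlaqueTruth(center=(2.2, 3.0, 1.75), radius=0.12, delta_r2star=0.25),
    PlaqueTruth(center=(3.8, 3.0, 2.25), radius=0.10, delta_r2star=0.30),
    PlaqueTruth(center=(3.0, 4.2, 2.75), radius=0.14, delta_r2star=0.22),
]


@pytest.fixture(scope="session")
def small_spec_noiseless() -> PhantomSpec:
    return PhantomSpec(plaques=list(SMALL_PLAQUES), noise_sigma=0.0, seed=0, **SMALL_KW)


@pytest.fixture(scope="session")
def small_phantom_noiseless(small_spec_noiseless):
    return generate_phantom(small_spec_noiseless)


@pytest.fixture(scope="session")
def small_spec_noisy() -> PhantomSpec:
    return PhantomSpec(plaques=list(SMALL_PLAQUES), noise_sigma=0.02, seed=0, **SMALL_KW)


@pytest.fixture(scope="session")
def small_phantom_noisy(small_spec_noisy):
    return generate_phantom(small_spec_noisy)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
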