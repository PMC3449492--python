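import numpy as np
import pytest

from modaspects import build_phantom_atlas, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    """Shared small phantom: 48^2 x 30 grid, 3 mm voxels, 450 ml SBV."""
    return build_phantom_atlas((48, 48, 30), (3.0, 3.0, 3.0), 450.0, seed=7)


@pytest.fixture(scope="session")
def childhood_atlas():
    return build_phantom_atlas((56, 56, 36), (3.2, 3.2, 3.2), 1050.0, seed=1)


@pytest.fixture(scope="session")
def perinatal_atlas():
    return build_phantom_atlas((56, 56, 36), (2.2, 2.2, 2.2), 350.0, seed=1)


@pytest.fixture(scope="session")
def childhood_cohort_500(childhood_atlas):
    return simulate_cohort(childhood_atlas, "childhood", 500, seed=202)


@pytest.fixture(scope="session")
def perinatal_cohort_500(perinatal_atlas):
    return simulate_cohort(perinatal_atlas, "perinatal", 500, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
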