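import numpy as np
import pytest

from lungdens import CohortSpec, VolumeSpec, generate_cohort, generate_volume


@pytest.fixture(scope="session")
def small_volume_spec():
    """A quick phantom: small grid, both structure types present."""
    return VolumeSpec(grid_shape=(24, 48, 48), seed=12)


@pytest.fixture(scope="session")
def small_volume(small_volume_spec):
    return generate_volume(small_volume_spec)


@pytest.fixture(scope="session")
def table_cohort():
    """Cohort with binary exposures fixed to the reference study's counts
    (41 cases / 48 controls, exact assignment)."""
    return generate_cohort(CohortSpec(seed=5, exact=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
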