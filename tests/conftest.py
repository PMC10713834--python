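import numpy as np
import pytest

from dkihabitat.synthetic_cohort import SimulationConfig, table1_fixture


@pytest.fixture(scope="session")
def small_config():
    """A small, fast cohort: 8 subjects on a 24^3 grid."""
    return SimulationConfig(
        seed=7,
        n_subjects=8,
        volume_shape=(24, 24, 24),
        geometry={"LH": (3.5, 3.5, 3.5), "LL": (6.0, 6.0, 6.0), "HL": (9.0, 9.0, 9.0), "HH": (2.0, 2.0, 2.0)},
        hh_offset=(4.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def fixture_records():
    return table1_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230317)
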