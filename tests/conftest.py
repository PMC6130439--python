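import numpy as np
import pytest

from negconn import SyntheticConfig, generate_cohort, load_gordon333
from negconn.cohort import toy_parcellation


@pytest.fixture(scope="session")
def gordon():
    return load_gordon333()


@pytest.fixture(scope="session")
def toy_parc():
    return toy_parcellation()


@pytest.fixture(scope="session")
def small_records():
    """Records-only cohort with the default planted effects (60/group)."""
    cfg = SyntheticConfig(seed=42, n_subjects_per_group=60)
    return generate_cohort(cfg, emit_timeseries=False).records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
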