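import numpy as np
import pytest

from neurocross import CohortSpec, generate_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    """Standard 7-network atlas on a downsampled template-scale grid."""
    return generate_atlas((24, 24, 12), 7, seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    """Smaller grid for decomposition tests (keeps ICA/sDL fast)."""
    return generate_atlas((16, 16, 8), 7, seed=2)


@pytest.fixture(scope="session")
def experiment_cohort(atlas):
    """6/6/6 sham-SLN-FMT cohort, time series only."""
    spec = CohortSpec(n_per_group={"sham": 6, "SLN": 6, "FMT": 6}, seed=11)
    return generate_cohort(spec, atlas)


@pytest.fixture(scope="session")
def healthy_cohort(atlas):
    """44-subject healthy cohort for the severity simulation."""
    spec = CohortSpec(n_per_group={"healthy": 44}, seed=13)
    return generate_cohort(spec, atlas)


def group_ts(cohort, group):
    return [r.node_ts for r in cohort if r.group == group]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
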