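import numpy as np
import pytest

from dbsfmri import PipelineConfig, Paradigm, make_default_atlas
from dbsfmri.pipeline import cohort_features


@pytest.fixture(scope="session")
def atlas():
    return make_default_atlas()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture
def small_paradigm():
    """Short session for fast I/O and pipeline tests: 35 volumes."""
    return Paradigm(lead_in_s=10.0, block_s=10.0, n_cycles=3, tr_s=2.0)


@pytest.fixture(scope="session")
def default_cohort_features(atlas, config):
    """Feature table of the full default synthetic cohort (seed 0).

    Computed once per session; this is the calibrated-simulation input for
    classification and group-analysis checks.
    """
    return cohort_features(config, seed=0, atlas=atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
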