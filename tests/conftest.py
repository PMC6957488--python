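import numpy as np
import pytest

from oxyflow import EpochSpec, StudyDesign, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def mini_config():
    """Short-epoch study conditions for fast cohort-level tests: the
    protocol structure is unchanged, only the epoch length is reduced."""
    return SyntheticConfig(epoch_minutes=(2.0, 2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def mini_spec(mini_config):
    return mini_config.epoch_spec


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    design = StudyDesign(ts_subjects=4, bc_subjects=4, seed=11)
    return generate_cohort(design, mini_config)


@pytest.fixture(scope="session")
def default_spec():
    return EpochSpec.from_minutes(30, 30, 30)
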