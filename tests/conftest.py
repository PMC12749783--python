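import numpy as np
import pytest
from hypothesis import settings

from tonescale.synthetic_study import StudyConfig, generate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """The default 64-participant synthetic study, generated once per run."""
    return generate(StudyConfig(master_seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A reduced cohort for fast pipeline plumbing tests."""
    cfg = StudyConfig(
        participants_per_fst=(2, 2, 2, 2, 2, 2),
        n_crowd_users=12,
        reads_per_image=5,
        patch_size=8,
        master_seed=7,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
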