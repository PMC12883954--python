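import numpy as np
import pytest

from fatnet.benchmark import prepare_run
from fatnet.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for plumbing tests (10 participants, short days)."""
    cfg = GeneratorConfig(n_participants=10, days_mean=12, days_sd=3, T=60, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def stats_cohort():
    """Medium cohort (~2400 participant-days) for statistical checks."""
    cfg = GeneratorConfig(n_participants=60, days_mean=40, days_sd=8, T=60, seed=21)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    """Scaled train/val/test SampleSets from the tiny cohort."""
    return prepare_run(small_cohort, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
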