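import numpy as np
import pytest

from cfpop.synth import generate_dataset, small_config


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 mice x 6 sessions x 12 neurons x 24 trials — fast shared fixture."""
    cfg = small_config(n_mice=2, neurons_per_session=12, trials_per_session=24)
    ds, truth = generate_dataset(cfg, seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def recovery_dataset():
    """Larger cohort used for planted-structure recovery checks."""
    cfg = small_config(n_mice=4)   # 4 x 6 sessions x 24 neurons x 30 trials
    ds, truth = generate_dataset(cfg, seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
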