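import numpy as np
import pytest

import t2demu as t
from t2demu.surrogate import SimulatorConfig, generate_dataset

# one grid enumeration for the whole session: it is deterministic and
# moderately expensive (46170 dataclass instances)
@pytest.fixture(scope="session")
def grid():
    return t.enumerate_grid()


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulatorConfig(noise_sd_beta=0.0, noise_sd_gamma=0.0, noise_sd_tau=0.0)


@pytest.fixture(scope="session")
def small_tables(grid):
    """60-subject design, split 70/30, simulated with the default noise."""
    sample = t.lhs_sample(grid, 60, seed=101)
    train_s, test_s = t.split_train_test(sample, 0.7, seed=102)
    cfg = SimulatorConfig()
    train = generate_dataset(train_s, cfg, seed=103)
    test = generate_dataset(test_s, cfg, seed=104)
    return train, test


@pytest.fixture(scope="session")
def small_fit(small_tables):
    train, _ = small_tables
    return t.fit_emulator(train, n_trees=20, seed=105)


@pytest.fixture(scope="session")
def example_subject(grid):
    """The optimization show-case: overweight average-height 38-year-old male,
    one 30-minute session per week at 60% VO2max, med/high/high diet."""
    return t.VirtualSubject(
        sex="male",
        age=38,
        weight_class="overweight",
        height_class="average",
        pa_sessions=1,
        pa_duration=30,
        pa_intensity=60,
        carb_level="med",
        prot_level="high",
        fat_level="high",
    )
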