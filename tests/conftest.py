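import numpy as np
import pytest

from connmvpa import (EdgeIndexMap, SimulationConfig, build_dataset,
                      simulate_cohort)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """16-subject, 20-region cohort with three strongly decreased edges."""
    cfg = SimulationConfig(n_patients=8, n_controls=8, n_regions=20,
                           n_timepoints=120,
                           planted_edges=((0, 1, -0.5), (2, 3, -0.5), (0, 5, -0.5)),
                           seed=3)
    return build_dataset(simulate_cohort(cfg)), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def edge_map_5():
    return EdgeIndexMap(5)
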