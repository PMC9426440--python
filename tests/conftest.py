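import numpy as np
import pytest

from mpcms1 import SimulationConfig, simulate_screen
from mpcms1.types import DesignTable, IntensityMatrix


@pytest.fixture
def small_matrix():
    """3 features x 4 samples with one absent entry."""
    values = np.array(
        [
            [10.0, 12.0, 9.0, 11.0],
            [100.0, np.nan, 95.0, 105.0],
            [1.0, 2.0, 1.5, 1.2],
        ]
    )
    return IntensityMatrix(
        values=values,
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        rt=np.array([10.0, 20.0, 30.0]),
        mz=np.array([400.0, 500.0, 600.0]),
    )


@pytest.fixture
def two_group_design():
    return DesignTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        condition=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen shared by the slower integration tests."""
    cfg = SimulationConfig(
        n_features=400,
        n_modules=6,
        module_size=50,
        conditions=[f"c{i}" for i in range(8)],
        condition_groups=[0, 0, 0, 1, 1, 2, 2, 2],
        replicates=3,
        seed=11,
    )
    return simulate_screen(cfg)
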