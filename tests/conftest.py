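import numpy as np
import pytest

from coenocycle import DivisionModel, InitialPloidyDistribution
from coenocycle.synthetic_data import ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def timer():
    """The study's timer: 11 h mean period, 10% cell-to-cell CV."""
    return DivisionModel(11.0, 0.10)


@pytest.fixture
def init_mixture():
    """Starvation-synchronized starting mixture of 1C/2C/4C cells."""
    return InitialPloidyDistribution({1.0: 0.25, 2.0: 0.50, 4.0: 0.25})


@pytest.fixture
def small_config():
    """Scaled-down experiment for fast unit tests (full sizes are exercised
    in the acceptance tests)."""
    return ExperimentConfig(
        n_cells=600,
        events_per_timepoint=800,
        microscopy_cells_per_timepoint=120,
        timelapse_cells_per_condition=8,
        seed=7,
    )
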