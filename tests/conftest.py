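import numpy as np
import pytest
from hypothesis import settings

from roadpm import ScenarioConfig, VariableGrid, generate_scenario

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: reduced scenario used wherever the full default would be wasteful
SMALL = dict(
    domain=(0.0, 0.0, 16000.0, 16000.0),
    years=(2000,),
    n_tracts=25,
    total_population=150_000.0,
)


@pytest.fixture
def small_config():
    return ScenarioConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(ScenarioConfig(seed=7, **SMALL), coarsest=8000.0)


@pytest.fixture
def uniform_grid_2x2():
    """Four 1-km cells tiling a 2 km square."""
    return VariableGrid(
        x0=np.array([0.0, 1000.0, 0.0, 1000.0]),
        y0=np.array([0.0, 0.0, 1000.0, 1000.0]),
        side=np.full(4, 1000.0),
        domain=(0.0, 0.0, 2000.0, 2000.0),
    )


@pytest.fixture
def mixed_grid():
    """One 2-km cell plus four 1-km cells tiling a 4 km x 2 km domain."""
    return VariableGrid(
        x0=np.array([0.0, 2000.0, 3000.0, 2000.0, 3000.0]),
        y0=np.array([0.0, 0.0, 0.0, 1000.0, 1000.0]),
        side=np.array([2000.0, 1000.0, 1000.0, 1000.0, 1000.0]),
        domain=(0.0, 0.0, 4000.0, 2000.0),
    )
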