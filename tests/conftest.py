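import numpy as np
import pytest

from gduplan.core import GduScenario, Instance, Population


@pytest.fixture
def simple_scenario():
    return GduScenario(label="s", weekly_gdu=[50, 80, 120, 150, 150, 120, 80, 50, 30, 20])


@pytest.fixture
def single_pop_instance(simple_scenario):
    pop = Population(
        id=1, earliest_plant_week=1, latest_plant_week=2,
        required_gdu=300.0, hq_case1=100.0, hq_case2=150.0,
    )
    return Instance(
        populations=[pop], scenarios=[simple_scenario], T=10, capacity=100.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
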