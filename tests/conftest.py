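import numpy as np
import pytest

import allostasim as al


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scenario_i():
    """Uncorrelated night/work rates with the reference gamma marginals."""
    return al.ScenarioSpec(
        scenario="I",
        work_rate_dist=al.WORK_QUANTITY_GAMMA,
        night_rate_dist=al.NIGHT_QUANTITY,
        coupling_dist=al.ANTICIPATION_COUPLING,
    )


@pytest.fixture
def scenario_ii():
    """Anticipation-coupled rates with uniform work-rate marginal."""
    return al.ScenarioSpec(
        scenario="II",
        work_rate_dist=al.WORK_QUANTITY_UNIFORM,
        night_rate_dist=al.NIGHT_QUANTITY,
        coupling_dist=al.ANTICIPATION_COUPLING,
    )


@pytest.fixture
def small_population(scenario_ii):
    return al.build_population(20, scenario_ii, al.DECAY_DISTRIBUTION, 99)
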