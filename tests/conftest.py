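import pytest

import nutrideb as nd


@pytest.fixture(scope="session")
def params():
    return nd.default_params()


@pytest.fixture(scope="session")
def diet(params):
    """Reference commercial feed: 45/22/19/14 with ADC 0.9/0.9/0.7."""
    return nd.default_diet(params)


@pytest.fixture(scope="session")
def yields(params, diet):
    return nd.coupling_yields(diet, params.reserve, params.digestion.kappa_A)


@pytest.fixture(scope="session")
def library():
    return nd.default_library()


def _run(params, diet, daily_fraction, meals_per_day, duration=30.0,
         n_fish=100):
    scenario = nd.Scenario(
        duration=duration, initial_weight=150.0, temperature=15.0,
        schedule=nd.FeedingSchedule.daily(duration, daily_fraction,
                                          meals_per_day, diet_id="ref"),
        diets={"ref": diet}, n_fish=n_fish)
    return nd.simulate(scenario, params)


@pytest.fixture(scope="session")
def run_12pct(params, diet):
    """30-d reference scenario: 1.2 % BW/d in one daily meal at 15 degC."""
    return _run(params, diet, 0.012, 1)


@pytest.fixture(scope="session")
def run_08pct(params, diet):
    return _run(params, diet, 0.008, 1)


@pytest.fixture(scope="session")
def run_3meals(params, diet):
    return _run(params, diet, 0.012, 3)
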