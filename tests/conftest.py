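import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

from codcast.series import AnnualSeries
from codcast.synthetic import default_config, make_scenario


@pytest.fixture(scope="session")
def scenario():
    """One realized default Barents-like scenario with its ground truth."""
    return make_scenario(default_config(seed=0))


@pytest.fixture(scope="session")
def dataset(scenario):
    return scenario[0]


@pytest.fixture(scope="session")
def truth(scenario):
    return scenario[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, start_year=1950, name="s") -> AnnualSeries:
    values = np.asarray(values, dtype=float)
    return AnnualSeries(name=name,
                        years=np.arange(start_year, start_year + len(values)),
                        values=values)


@pytest.fixture()
def series_factory():
    return make_series
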