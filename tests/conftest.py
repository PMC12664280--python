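import pytest
from hypothesis import HealthCheck, settings

from espdisc import sigpred, simulate

settings.register_profile(
    "espdisc",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("espdisc")


@pytest.fixture(scope="session")
def predictor():
    return sigpred.HeuristicPredictor()


@pytest.fixture(scope="session")
def population():
    """A small synthetic population shared across tests."""
    return simulate.make_population(40, seed=11)
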