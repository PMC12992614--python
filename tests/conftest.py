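import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phylodisp import simulate as sim

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic study at n=80 with the reference generative condition."""
    return sim.simulate_dataset(sim.SimulationConfig(n=80, seed=11))


@pytest.fixture(scope="session")
def three_leaf_tree():
    from phylodisp import trees as ph

    return ph.read_trees("((A:1,B:1):1,C:2);")[0]


@pytest.fixture(autouse=True)
def _quiet_warnings(recwarn):
    # degeneracy / exclusion warnings are expected in many scenarios
    yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
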