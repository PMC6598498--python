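import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netdiffstat import CorrelationNetwork, GroupedData

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_network(adjacency, names=None, label="") -> CorrelationNetwork:
    A = np.asarray(adjacency, dtype=float)
    if names is None:
        names = [f"v{i}" for i in range(A.shape[0])]
    return CorrelationNetwork(adjacency=A, node_names=list(names), group_label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_group_data(rng) -> GroupedData:
    """20 samples, 6 variables, two groups, no real group difference."""
    values = rng.normal(size=(20, 6))
    labels = np.repeat(["a", "b"], 10)
    return GroupedData.from_arrays(values, labels)


@pytest.fixture
def three_group_data(rng) -> GroupedData:
    values = rng.normal(size=(30, 5))
    labels = np.repeat(["x", "y", "z"], 10)
    return GroupedData.from_arrays(values, labels)
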