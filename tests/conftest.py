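import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bridgenet as bn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    """Default planted two-community network (5 anxiety + 9 IGD nodes)."""
    return bn.make_true_network()


@pytest.fixture(scope="session")
def reference_network(default_spec):
    """Network whose only edges are the 23 default cross-community weights.

    Within-community weights are zeroed so bridge statistics depend on the
    cross-community block alone.
    """
    labels = list(default_spec.labels)
    idx = {l: i for i, l in enumerate(labels)}
    W = np.zeros((14, 14))
    for a, b, w in bn.DEFAULT_CROSS_EDGES:
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return bn.PartialCorrelationNetwork(
        labels=labels,
        weights=W,
        community_of_node=dict(default_spec.community_of_node),
        n=667,
    )


@pytest.fixture(scope="session")
def cohort2000(default_spec):
    """Reference synthetic cohort: n=2000, seed 0."""
    return bn.simulate_cohort(default_spec, 2000, seed=0)


@pytest.fixture(scope="session")
def net2000(cohort2000):
    """EBIC-selected network of the reference cohort (default settings)."""
    return bn.estimate_network(cohort2000.scores)
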