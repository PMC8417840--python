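from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort_spec():
    """Reduced cohort for fast integration tests: 30 nodes, 3 modules."""
    from fcnetopo.cohort import CohortSpec

    return CohortSpec(
        n_nodes=30,
        n_modules=3,
        group_sizes={"WC": 3, "DR": 4, "CTRL": 5},
        seed=7,
    )


@pytest.fixture
def star_graph():
    """Center node 0 with four unit-weight spokes."""
    from fcnetopo.graph import WeightedGraph

    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 1.0
    return WeightedGraph(W)


@pytest.fixture
def complete_unit_graph():
    from fcnetopo.graph import WeightedGraph

    W = np.ones((4, 4)) - np.eye(4)
    return WeightedGraph(W)


@pytest.fixture
def chain_graph():
    """3-node chain with weights 0.5 and 0.25 (lengths 2 and 4)."""
    from fcnetopo.graph import WeightedGraph

    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.25
    return WeightedGraph(W)
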