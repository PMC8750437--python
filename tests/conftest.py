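import numpy as np
import pandas as pd
import pytest

from phasenet import (
    SimulationConfig,
    make_ground_truth,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale three-phase cohort: 60 genes, 5 hubs, full 87-sample design."""
    return SimulationConfig(
        n_genes=60, n_hubs=5, out_degree_range=(3, 5), seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return make_ground_truth(small_cfg)


@pytest.fixture(scope="session")
def small_data(small_cfg, small_truth):
    matrix, meta = simulate_expression(small_truth, small_cfg)
    return matrix, meta


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 6.0], [-0.5, 0.25]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
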