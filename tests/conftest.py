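import pandas as pd
import pytest

from edaphonet.datatypes import OtuTable
from edaphonet.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic bundle shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_otus=80, sequencing_depth=5000,
                           depth_cv=0.2)
    return generate_dataset(cfg)


@pytest.fixture
def tiny_table():
    """4 samples x 3 OTUs with hand-set counts."""
    counts = pd.DataFrame(
        [[10, 0, 5], [8, 1, 6], [12, 2, 4], [9, 3, 7]],
        index=[f"s{i}" for i in range(1, 5)],
        columns=["OTU_a", "OTU_b", "OTU_c"],
    )
    return OtuTable(counts)


def random_graph(rng, max_nodes=8):
    """Random small graph as (nodes, edge list)."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.2, 0.8)
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
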