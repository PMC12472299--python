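import numpy as np
import pandas as pd
import pytest

from litterome import simulate as sim
from litterome.containers import CommunityTable


@pytest.fixture(scope="session")
def tree20():
    return sim.simulate_tree(20, 123)


@pytest.fixture(scope="session")
def tree50():
    return sim.simulate_tree(50, 7)


@pytest.fixture(scope="session")
def neutral_table(tree20):
    cfg = sim.SimulationConfig(
        n_taxa=20, n_samples_per_group=5, groups=("A", "B", "C"),
        depth=1000, seed=11,
    )
    table, truth = sim.simulate_communities(cfg, tree=tree20)
    return table, truth


@pytest.fixture(scope="session")
def toy5_distances():
    """Hand-built cophenetic matrix over 5 taxa (ultrametric, depth 4)."""
    taxa = list("ABCDE")
    d = np.array(
        [
            [0, 2, 4, 8, 8],
            [2, 0, 4, 8, 8],
            [4, 4, 0, 8, 8],
            [8, 8, 8, 0, 3],
            [8, 8, 8, 3, 0],
        ],
        dtype=float,
    )
    return pd.DataFrame(d, index=taxa, columns=taxa)


@pytest.fixture
def toy5_table():
    counts = pd.DataFrame(
        [
            [5, 3, 0, 2, 0],
            [0, 4, 4, 0, 2],
            [1, 0, 0, 6, 3],
            [2, 2, 2, 2, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=list("ABCDE"),
    )
    return CommunityTable(counts=counts)
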