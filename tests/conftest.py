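import networkx as nx
import pytest

import sharedcare as sc


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 4-SCA x 10-ZCTA dataset with one hospital per ZCTA."""
    return sc.generate_dataset(sc.SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def gee_dataset():
    """300-hospital panel for regression checks (50 SCAs keep the full
    adjusted design full-rank)."""
    cfg = sc.SyntheticConfig(
        n_scas=50, zctas_per_sca=6, hospitals_per_sca=6, between_rate=0.2, seed=7
    )
    return sc.generate_dataset(cfg)


@pytest.fixture
def two_cliques():
    G = nx.Graph()
    for offset in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                G.add_edge(offset + i, offset + j, weight=1.0)
    G.graph["year"] = 2012
    return G
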