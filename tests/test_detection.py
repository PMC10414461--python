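"""Community-detection unit and property tests.

Oracles: exhaustive enumeration over set partitions, naive double-loop
modularity, and the entropy-form map equation (tests/helpers.py).
"""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import sharedcare as sc
from helpers import (
    blocks_to_labels,
    naive_codelength,
    naive_modularity,
    set_partitions,
    two_block_graph,
)


def _ari(partition, truth_labels):
    nodes = list(truth_labels)
    return adjusted_rand_score(
        [truth_labels[u] for u in nodes], [partition.labels[u] for u in nodes]
    )


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def test_modularity_closed_forms(two_cliques):
    one = {u: 0 for u in two_cliques}
    assert sc.modularity(two_cliques, one) == pytest.approx(0.0, abs=1e-12)
    split = {u: u // 4 for u in two_cliques}
    assert sc.modularity(two_cliques, split) == pytest.approx(0.5, abs=1e-12)


def test_modularity_matches_naive_double_loop():
    rng = np.random.default_rng(0)
    G = nx.gnm_random_graph(20, 60, seed=1)
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.integers(1, 9))
    G.add_edge(3, 3, weight=4.0)  # self-loop coverage
    labels = {u: int(rng.integers(0, 4)) for u in G}
    for resolution in (0.5, 1.0, 2.0):
        assert sc.modularity(G, labels, resolution) == pytest.approx(
            naive_modularity(G, labels, resolution), abs=1e-12
        )


def test_modularity_agrees_with_networkx():
    rng = np.random.default_rng(2)
    G = nx.gnm_random_graph(15, 40, seed=3)
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.integers(1, 6))
    labels = {u: int(rng.integers(0, 3)) for u in G}
    comms = [{u for u in G if labels[u] == c} for c in set(labels.values())]
    expected = nx.community.modularity(G, comms, weight="weight")
    assert sc.modularity(G, labels) == pytest.approx(expected, abs=1e-12)


def test_modularity_missing_node_raises(two_cliques):
    with pytest.raises(ValueError, match="missing"):
        sc.modularity(two_cliques, {0: 0})


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------


def test_louvain_disconnected_triangles():
    G = nx.Graph()
    for offset in (0, 3):
        for i in range(3):
            for j in range(i + 1, 3):
                G.add_edge(offset + i, offset + j, weight=1.0)
    part = sc.louvain(G, sc.DetectionConfig(seed=0))
    assert part.n_communities == 2
    assert len({part.labels[0], part.labels[1], part.labels[2]}) == 1
    assert len({part.labels[3], part.labels[4], part.labels[5]}) == 1


def test_louvain_matches_exhaustive_maximum_on_8_nodes():
    """Search optimum equals the maximum over all 4,140 set partitions."""
    G = two_block_graph(n_per_block=4, within=5.0, between=1.0)
    best = max(
        sc.modularity(G, blocks_to_labels(blocks)) for blocks in set_partitions(G.nodes)
    )
    part = sc.louvain(G, sc.DetectionConfig(seed=0))
    assert sc.modularity(G, part) == pytest.approx(best, abs=1e-12)


def test_louvain_huge_resolution_gives_singletons(two_cliques):
    two_cliques.add_edge(0, 4, weight=1.0)  # connect the cliques
    part = sc.louvain(two_cliques, sc.DetectionConfig(resolution=1000.0, seed=0))
    assert part.n_communities == two_cliques.number_of_nodes()


def test_louvain_improves_on_trivial_partitions():
    G = two_block_graph(n_per_block=5, within=4.0, between=1.0)
    part = sc.louvain(G, sc.DetectionConfig(seed=1))
    q = sc.modularity(G, part)
    assert q >= sc.modularity(G, {u: 0 for u in G}) - 1e-12
    assert q >= sc.modularity(G, {u: u for u in G}) - 1e-12


# ---------------------------------------------------------------------------
# SLPA
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_slpa_recovers_disconnected_cliques(two_cliques, seed):
    part = sc.slpa(two_cliques, sc.DetectionConfig(algorithm="slpa", seed=seed))
    assert _ari(part, {u: u // 4 for u in two_cliques}) == 1.0


def test_slpa_threshold_one_still_assigns_every_node(two_cliques):
    two_cliques.add_edge(0, 4, weight=0.5)
    cfg = sc.DetectionConfig(algorithm="slpa", slpa_threshold=1.0, seed=3)
    part = sc.slpa(two_cliques, cfg)
    assert set(part.labels) == set(two_cliques.nodes)
    assert all(isinstance(v, int) for v in part.labels.values())


def test_slpa_planted_recovery_mean_ari(small_dataset):
    """Planted 4-block network: mean ARI over 20 seeds at least 0.9."""
    G = sc.build_network(small_dataset.flows, 2014)
    scores = [
        _ari(sc.slpa(G, sc.DetectionConfig(algorithm="slpa", seed=s)), small_dataset.labels)
        for s in range(20)
    ]
    assert np.mean(scores) >= 0.9


# ---------------------------------------------------------------------------
# map equation
# ---------------------------------------------------------------------------


def test_mapeq_codelength_matches_entropy_oracle():
    rng = np.random.default_rng(4)
    G = nx.gnm_random_graph(12, 30, seed=5)
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.integers(1, 7))
    for _ in range(5):
        labels = {u: int(rng.integers(0, 3)) for u in G}
        assert sc.map_equation_codelength(G, labels) == pytest.approx(
            naive_codelength(G, labels), abs=1e-12
        )


def test_mapeq_one_module_codelength_is_visit_rate_entropy(two_cliques):
    two_w = sum(k for _, k in two_cliques.degree(weight="weight"))
    ps = [k / two_w for _, k in two_cliques.degree(weight="weight")]
    entropy = -sum(p * np.log2(p) for p in ps)
    L = sc.map_equation_codelength(two_cliques, {u: 0 for u in two_cliques})
    assert L == pytest.approx(entropy, abs=1e-12)


def test_mapeq_two_cliques(two_cliques):
    part = sc.mapeq_two_level(two_cliques, sc.DetectionConfig(algorithm="mapeq", seed=0))
    assert _ari(part, {u: u // 4 for u in two_cliques}) == 1.0
    L_two = sc.map_equation_codelength(two_cliques, part)
    L_one = sc.map_equation_codelength(two_cliques, {u: 0 for u in two_cliques})
    assert L_two < L_one


def test_mapeq_matches_exhaustive_minimum_on_10_nodes():
    """Search optimum equals the minimum over all 2-4 block partitions."""
    G = two_block_graph(n_per_block=5, within=5.0, between=1.0)
    best = min(
        naive_codelength(G, blocks_to_labels(blocks))
        for blocks in set_partitions(G.nodes)
        if 2 <= len(blocks) <= 4
    )
    part = sc.mapeq_two_level(G, sc.DetectionConfig(algorithm="mapeq", seed=0))
    assert naive_codelength(G, part.labels) == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# cross-algorithm properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("algorithm", ["louvain", "slpa", "mapeq"])
def test_union_of_cliques_identical_structure(two_cliques, algorithm):
    cfg = sc.DetectionConfig(algorithm=algorithm, seed=2)
    part = sc.detect(two_cliques, cfg)
    assert _ari(part, {u: u // 4 for u in two_cliques}) == 1.0


@pytest.mark.parametrize("algorithm", ["louvain", "slpa", "mapeq"])
def test_seed_determinism(small_dataset, algorithm):
    G = sc.build_network(small_dataset.flows, 2013)
    cfg = sc.DetectionConfig(algorithm=algorithm, seed=11)
    assert sc.detect(G, cfg).labels == sc.detect(G, cfg).labels


def test_isolated_node_forms_own_sca():
    G = nx.Graph()
    G.add_edge("a", "b", weight=3.0)
    G.add_node("c")
    for algorithm in ("louvain", "mapeq", "slpa"):
        part = sc.detect(G, sc.DetectionConfig(algorithm=algorithm, seed=0))
        assert part.labels["c"] not in {part.labels["a"], part.labels["b"]}


def test_empty_network_rejected():
    for fn in (sc.louvain, sc.slpa, sc.mapeq_two_level):
        with pytest.raises(ValueError, match="empty"):
            fn(nx.Graph())


# ---------------------------------------------------------------------------
# relabel
# ---------------------------------------------------------------------------


def test_relabel_example_and_idempotence():
    part = sc.Partition(year=2012, algorithm="x", labels={"a": 7, "b": 7, "c": 2})
    out = part.relabel()
    assert out.labels == {"a": 0, "b": 0, "c": 1}
    assert out.relabel().labels == out.labels


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=30))
def test_relabel_preserves_equivalence_classes(raw):
    labels = {f"z{i}": lab for i, lab in enumerate(raw)}
    part = sc.Partition(year=0, algorithm="x", labels=labels)
    out = part.relabel()

    def classes(lab):
        groups = {}
        for node, c in lab.items():
            groups.setdefault(c, set()).add(node)
        return sorted(map(frozenset, groups.values()), key=sorted)

    assert classes(out.labels) == classes(labels)
    assert set(out.labels.values()) == set(range(len(set(raw))))
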