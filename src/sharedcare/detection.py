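"""Community detection on yearly discharge networks.

Shared care areas (SCAs) are delineated as communities of a weighted,
undirected ZCTA-level discharge network.  Three algorithms are provided:

* :func:`louvain` — greedy multi-level maximization of weighted modularity
  with a resolution parameter (default 1);
* :func:`slpa` — speaker–listener label propagation with a membership
  frequency threshold (default 0.5) and a crisp projection, since the
  localization index requires disjoint SCAs;
* :func:`mapeq_two_level` — greedy multi-level minimization of the two-level
  map equation with strength-proportional random-walk visit rates.

All three are seeded and deterministic for a fixed (network, config, seed).
Candidate moves only consider communities adjacent to a node, so connected
components are processed independently and an isolated node forms its own
SCA.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "DetectionConfig",
    "Partition",
    "louvain",
    "slpa",
    "mapeq_two_level",
    "modularity",
    "map_equation_codelength",
    "relabel",
    "detect",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DetectionConfig:
    """Configuration shared by the detection algorithms.

    Parameters
    ----------
    algorithm:
        One of ``louvain``, ``slpa``, ``mapeq``.
    resolution:
        Louvain resolution gamma > 0; larger values favour smaller
        communities.
    slpa_iterations:
        Number of speaker-listener rounds (also the label-memory length
        added on top of the initial own label).
    slpa_threshold:
        Post-processing membership frequency threshold in (0, 1].
    seed:
        Seed for node-visit shuffles, speaker sampling and tie-breaks.
    """

    algorithm: str = "louvain"
    resolution: float = 1.0
    slpa_iterations: int = 100
    slpa_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in {"louvain", "slpa", "mapeq"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.resolution > 0:
            raise ValueError("resolution must be > 0")
        if not (0 < self.slpa_threshold <= 1):
            raise ValueError("slpa_threshold must be in (0, 1]")
        if self.slpa_iterations < 1:
            raise ValueError("slpa_iterations must be >= 1")


@dataclass
class Partition:
    """Disjoint assignment of every ZCTA to one SCA for one year/algorithm."""

    year: int
    algorithm: str
    labels: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> dict:
        comms = defaultdict(set)
        for node, lab in self.labels.items():
            comms[lab].add(node)
        return dict(comms)

    def relabel(self) -> "Partition":
        """Map labels to 0..K-1 in order of first appearance (idempotent)."""
        mapping: dict = {}
        new = {}
        for node, lab in self.labels.items():
            if lab not in mapping:
                mapping[lab] = len(mapping)
            new[node] = mapping[lab]
        return replace(self, labels=new)


def relabel(partition: Partition) -> Partition:
    return partition.relabel()


# ---------------------------------------------------------------------------
# shared graph plumbing
# ---------------------------------------------------------------------------


def _adjacency(G: nx.Graph):
    """Return (adj, loops) with adj[u][v] = w for u != v and loop weights."""
    adj = {u: {} for u in G}
    loops = {u: 0.0 for u in G}
    for u, v, w in G.edges(data="weight", default=1.0):
        if u == v:
            loops[u] += float(w)
        else:
            adj[u][v] = adj[u].get(v, 0.0) + float(w)
            adj[v][u] = adj[v].get(u, 0.0) + float(w)
    return adj, loops


def _require_nonempty(G: nx.Graph) -> None:
    if G.number_of_nodes() == 0:
        raise ValueError("network is empty")


def _partition_from_assignment(G, assignment, algorithm) -> Partition:
    year = G.graph.get("year", -1)
    part = Partition(year=int(year), algorithm=algorithm, labels=dict(assignment))
    return part.relabel()


def _choose(rng: np.random.Generator, candidates):
    """Seeded uniform choice used for every tie-break."""
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# modularity and Louvain
# ---------------------------------------------------------------------------


def modularity(G: nx.Graph, partition, resolution: float = 1.0) -> float:
    """Weighted modularity Q = sum_c [ w_c/W - gamma (s_c / 2W)^2 ].

    ``w_c`` is the internal weight of community c (self-loops counted once),
    ``s_c`` the total strength of its nodes (self-loops counted twice) and
    ``W`` the total edge weight of the graph.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    missing = [u for u in G if u not in labels]
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(missing)[:5]}")
    W = G.size(weight="weight")
    if W <= 0:
        return 0.0
    internal = defaultdict(float)
    strength = defaultdict(float)
    for u, k in G.degree(weight="weight"):
        strength[labels[u]] += k
    for u, v, w in G.edges(data="weight", default=1.0):
        if labels[u] == labels[v]:
            internal[labels[u]] += w
    q = 0.0
    for c in strength:
        q += internal.get(c, 0.0) / W - resolution * (strength[c] / (2.0 * W)) ** 2
    return q


def _louvain_one_level(adj, loops, strength, labels, two_m, resolution, rng):
    """In-place local moving phase; returns True if any node moved."""
    nodes = list(adj)
    comm_tot = defaultdict(float)
    for u in nodes:
        comm_tot[labels[u]] += strength[u]
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = [nodes[i] for i in rng.permutation(len(nodes))]
        for u in order:
            a = labels[u]
            k_u = strength[u]
            w_to = defaultdict(float)
            for v, w in adj[u].items():
                w_to[labels[v]] += w
            comm_tot[a] -= k_u
            # gain(c) proportional to k_{u,c} - gamma * s_c * k_u / (2W)
            best_gain = w_to.get(a, 0.0) - resolution * comm_tot[a] * k_u / two_m
            best = [a]
            for c, w_uc in w_to.items():
                if c == a:
                    continue
                gain = w_uc - resolution * comm_tot[c] * k_u / two_m
                if gain > best_gain + _EPS:
                    best_gain = gain
                    best = [c]
                elif abs(gain - best_gain) <= _EPS and c not in best:
                    best.append(c)
            target = a if a in best else _choose(rng, sorted(best))
            comm_tot[target] += k_u
            if target != a:
                labels[u] = target
                moved_any = True
                improved = True
    return moved_any


def _aggregate(adj, loops, labels, extra=None):
    """Collapse communities into supernodes; returns new (adj, loops, mapping).

    ``extra`` is an optional per-node dict of additive quantities to carry
    through the aggregation (used for visit rates in the map equation).
    """
    comms = sorted(set(labels.values()))
    new_adj = {c: {} for c in comms}
    new_loops = {c: 0.0 for c in comms}
    new_extra = {c: 0.0 for c in comms} if extra is not None else None
    for u, nbrs in adj.items():
        cu = labels[u]
        new_loops[cu] += loops[u]
        if extra is not None:
            new_extra[cu] += extra[u]
        for v, w in nbrs.items():
            cv = labels[v]
            if cu == cv:
                if u < v:  # count each internal pair once
                    new_loops[cu] += w
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, new_loops, new_extra


def louvain(G: nx.Graph, config: DetectionConfig | None = None) -> Partition:
    """Multi-level modularity maximization (Louvain method).

    Local moves are accepted only when they strictly increase modularity, so
    the objective is monotone non-decreasing across accepted moves and
    aggregation levels; the search stops when a full level produces no move.
    """
    config = config or DetectionConfig(algorithm="louvain")
    _require_nonempty(G)
    rng = np.random.default_rng(config.seed)
    adj, loops = _adjacency(G)
    two_m = 2.0 * G.size(weight="weight")
    if two_m <= 0:
        # no edges: every node is its own community
        return _partition_from_assignment(G, {u: u for u in G}, "louvain")
    strength = {u: sum(adj[u].values()) + 2.0 * loops[u] for u in adj}
    assignment = {u: u for u in G}  # node -> community in the original graph
    labels = {u: u for u in adj}
    while True:
        moved = _louvain_one_level(
            adj, loops, strength, labels, two_m, config.resolution, rng
        )
        if not moved:
            break
        assignment = {u: labels[assignment[u]] for u in assignment}
        adj, loops, _ = _aggregate(adj, loops, labels)
        strength = {u: sum(adj[u].values()) + 2.0 * loops[u] for u in adj}
        labels = {u: u for u in adj}
    return _partition_from_assignment(G, assignment, "louvain")


# ---------------------------------------------------------------------------
# speaker-listener label propagation
# ---------------------------------------------------------------------------


def slpa(G: nx.Graph, config: DetectionConfig | None = None) -> Partition:
    """Speaker–listener label propagation with crisp post-processing.

    Each node keeps a label memory initialized to its own label.  For each
    round, listeners (in seeded shuffled order) collect one label from every
    neighbor — the speaker emits a label sampled uniformly from its memory —
    and adopt the heard label with the largest total edge weight (ties broken
    by seeded choice), appending it to memory.  Post-processing keeps labels
    whose memory frequency reaches ``slpa_threshold``; the crisp SCA label is
    the most frequent retained label (seeded tie-break).  Votes are weighted
    by edge weight so that strong within-SCA links dominate the many weak
    cross-SCA links typical of discharge networks.
    """
    config = config or DetectionConfig(algorithm="slpa")
    _require_nonempty(G)
    rng = np.random.default_rng(config.seed)
    nodes = list(G)
    index = {u: i for i, u in enumerate(nodes)}
    nbrs = []
    for u in nodes:
        pairs = [
            (index[v], float(d.get("weight", 1.0)))
            for v, d in G[u].items()
            if v != u
        ]
        nbrs.append(pairs)
    memory = [[i] for i in range(len(nodes))]

    for _ in range(config.slpa_iterations):
        order = rng.permutation(len(nodes))
        for li in order:
            pairs = nbrs[li]
            if not pairs:
                continue
            lens = np.array([len(memory[v]) for v, _ in pairs])
            picks = rng.integers(lens)
            votes = defaultdict(float)
            for (v, w), p in zip(pairs, picks):
                votes[memory[v][p]] += w
            top = max(votes.values())
            winners = sorted(l for l, w in votes.items() if w >= top - _EPS)
            memory[li].append(_choose(rng, winners))

    assignment = {}
    mem_len = config.slpa_iterations + 1
    for i, u in enumerate(nodes):
        counts = defaultdict(int)
        for lab in memory[i]:
            counts[lab] += 1
        retained = {
            lab: c for lab, c in counts.items() if c / len(memory[i]) >= config.slpa_threshold
        }
        pool = retained if retained else counts
        top = max(pool.values())
        winners = sorted(lab for lab, c in pool.items() if c == top)
        assignment[u] = _choose(rng, winners)
    del mem_len
    return _partition_from_assignment(G, assignment, "slpa")


# ---------------------------------------------------------------------------
# two-level map equation
# ---------------------------------------------------------------------------


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


def map_equation_codelength(G: nx.Graph, partition) -> float:
    """Two-level map equation L(M) = q H(Q) + sum_m p_m H(P_m).

    Visit rates are proportional to node strength (undirected random walk,
    no teleportation); module exit rates are the normalized weight of edges
    leaving the module.  Computed directly from the graph — used both by the
    search and as a stand-alone score.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    two_w = sum(k for _, k in G.degree(weight="weight"))
    if two_w <= 0:
        return 0.0
    p_node = {u: k / two_w for u, k in G.degree(weight="weight")}
    q_mod = defaultdict(float)
    p_mod = defaultdict(float)
    for u in G:
        p_mod[labels[u]] += p_node[u]
    for u, v, w in G.edges(data="weight", default=1.0):
        if u != v and labels[u] != labels[v]:
            q_mod[labels[u]] += w / two_w
            q_mod[labels[v]] += w / two_w
    q_tot = sum(q_mod.values())
    L = _plogp(q_tot)
    for m in p_mod:
        qm = q_mod.get(m, 0.0)
        L -= 2.0 * _plogp(qm)
        L += _plogp(qm + p_mod[m])
    L -= sum(_plogp(p) for p in p_node.values())
    return L


def _mapeq_one_level(adj, p_node, labels, two_w, rng):
    """Local moving phase minimizing the two-level codelength in place."""
    nodes = list(adj)
    q_mod = defaultdict(float)  # exit rate per module
    p_mod = defaultdict(float)  # visit rate per module
    for u in nodes:
        p_mod[labels[u]] += p_node[u]
    for u, nbrs in adj.items():
        for v, w in nbrs.items():
            if labels[u] != labels[v]:
                q_mod[labels[u]] += w / two_w
    # q_mod currently counts each boundary edge once per endpoint module: OK.

    def term(m, q, p):
        return -2.0 * _plogp(q) + _plogp(q + p)

    moved_any = False
    improved = True
    while improved:
        improved = False
        order = [nodes[i] for i in rng.permutation(len(nodes))]
        for u in order:
            a = labels[u]
            k_ext = sum(adj[u].values())  # strength excluding self-loops
            w_to = defaultdict(float)
            for v, w in adj[u].items():
                w_to[labels[v]] += w
            q_tot = sum(q_mod.values())
            # removing u from a
            qa_new = q_mod[a] - (k_ext - 2.0 * w_to.get(a, 0.0)) / two_w
            pa_new = p_mod[a] - p_node[u]
            if pa_new < _EPS:
                qa_new = 0.0
                pa_new = 0.0
            base_terms = term(a, q_mod[a], p_mod[a])
            best_delta = 0.0
            best = [a]
            for b in w_to:
                if b == a:
                    continue
                qb_new = q_mod[b] + (k_ext - 2.0 * w_to[b]) / two_w
                pb_new = p_mod[b] + p_node[u]
                q_tot_new = q_tot - q_mod[a] - q_mod[b] + qa_new + qb_new
                delta = (
                    _plogp(q_tot_new)
                    - _plogp(q_tot)
                    + term(a, qa_new, pa_new)
                    + term(b, qb_new, pb_new)
                    - base_terms
                    - term(b, q_mod[b], p_mod[b])
                )
                if delta < best_delta - _EPS:
                    best_delta = delta
                    best = [b]
                elif best != [a] and abs(delta - best_delta) <= _EPS:
                    best.append(b)
            if best != [a]:
                b = _choose(rng, sorted(best))
                qb_new = q_mod[b] + (k_ext - 2.0 * w_to[b]) / two_w
                q_mod[a] = qa_new
                p_mod[a] = pa_new
                q_mod[b] = qb_new
                p_mod[b] += p_node[u]
                labels[u] = b
                moved_any = True
                improved = True
    return moved_any


def mapeq_two_level(G: nx.Graph, config: DetectionConfig | None = None) -> Partition:
    """Greedy multi-level search minimizing the two-level map equation.

    Only strictly improving moves are accepted, so the codelength is
    monotone non-increasing during the search.
    """
    config = config or DetectionConfig(algorithm="mapeq")
    _require_nonempty(G)
    rng = np.random.default_rng(config.seed)
    adj, loops = _adjacency(G)
    two_w = sum(sum(n.values()) for n in adj.values()) + 2.0 * sum(loops.values())
    if two_w <= 0:
        return _partition_from_assignment(G, {u: u for u in G}, "mapeq")
    p_node = {u: (sum(adj[u].values()) + 2.0 * loops[u]) / two_w for u in adj}
    assignment = {u: u for u in G}
    labels = {u: u for u in adj}
    while True:
        moved = _mapeq_one_level(adj, p_node, labels, two_w, rng)
        if not moved:
            break
        assignment = {u: labels[assignment[u]] for u in assignment}
        adj, loops, p_agg = _aggregate(adj, loops, labels, extra=p_node)
        p_node = p_agg
        labels = {u: u for u in adj}
    return _partition_from_assignment(G, assignment, "mapeq")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_ALGORITHMS = {"louvain": louvain, "slpa": slpa, "mapeq": mapeq_two_level}


def detect(G: nx.Graph, config: DetectionConfig) -> Partition:
    """Run the algorithm named in ``config`` on the network."""
    return _ALGORITHMS[config.algorithm](G, config)
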