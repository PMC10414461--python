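"""Independent oracles for the test-suite.

Everything here recomputes quantities by brute force (enumeration, naive
double loops, direct entropy formulas) and is deliberately kept separate
from the implementation it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def set_partitions(items):
    """Yield every partition of ``items`` as a list of blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def blocks_to_labels(blocks):
    return {node: i for i, block in enumerate(blocks) for node in block}


def naive_modularity(G: nx.Graph, labels, resolution=1.0):
    """Double-loop modularity over node pairs with the adjacency convention
    A_ii = 2 * self-loop weight."""
    nodes = list(G)
    W = G.size(weight="weight")
    k = dict(G.degree(weight="weight"))
    q = 0.0
    for u in nodes:
        for v in nodes:
            if labels[u] != labels[v]:
                continue
            w = G[u][v]["weight"] if G.has_edge(u, v) else 0.0
            if u == v:
                w *= 2.0
            q += w / (2.0 * W) - resolution * k[u] * k[v] / (2.0 * W) ** 2
    return q


def naive_codelength(G: nx.Graph, labels):
    """Two-level map equation straight from its entropy definition:
    L = q H(Q) + sum_m p_m_circ H(P_m), visit rates by node strength."""

    def entropy(ps):
        tot = sum(ps)
        return -sum(p / tot * math.log2(p / tot) for p in ps if p > 0) if tot > 0 else 0.0

    two_w = sum(k for _, k in G.degree(weight="weight"))
    p = {u: k / two_w for u, k in G.degree(weight="weight")}
    modules = sorted(set(labels.values()))
    q_exit = {m: 0.0 for m in modules}
    for u, v, w in G.edges(data="weight", default=1.0):
        if u != v and labels[u] != labels[v]:
            q_exit[labels[u]] += w / two_w
            q_exit[labels[v]] += w / two_w
    q_tot = sum(q_exit.values())
    L = q_tot * entropy([q_exit[m] for m in modules])
    for m in modules:
        inside = [p[u] for u in G if labels[u] == m]
        circ = q_exit[m] + sum(inside)
        L += circ * entropy([q_exit[m]] + inside)
    return L


def brute_force_li(flow_rows, labels):
    """LI per SCA by plain enumeration over (origin, hospital, count) rows."""
    resident, internal = {}, {}
    for origin, hosp_zcta, count in flow_rows:
        s = labels[origin]
        resident[s] = resident.get(s, 0) + count
        if labels[hosp_zcta] == s:
            internal[s] = internal.get(s, 0) + count
    return {
        s: internal.get(s, 0) / resident[s] for s in resident if resident[s] > 0
    }


def hazen_percentile(values, pct):
    """Type-5 (Hazen) percentile by direct interpolation on sorted values."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    h = n * pct / 100.0 + 0.5
    h = min(max(h, 1.0), float(n))
    lo = int(math.floor(h))
    frac = h - lo
    if lo >= n:
        return float(xs[-1])
    return float(xs[lo - 1] + frac * (xs[lo] - xs[lo - 1]))


def two_block_graph(n_per_block=4, within=5.0, between=1.0, blocks=2):
    """Planted weighted block graph: dense strong blocks, weak bridges."""
    G = nx.Graph()
    n = n_per_block * blocks
    for i in range(n):
        G.add_node(i)
    for i in range(n):
        for j in range(i + 1, n):
            same = i // n_per_block == j // n_per_block
            w = within if same else (between if (i + j) % n_per_block == 0 else 0.0)
            if w > 0:
                G.add_edge(i, j, weight=w)
    return G
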