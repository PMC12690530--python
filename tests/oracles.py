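"""Independent brute-force oracles for the graph metrics.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: betweenness by exhaustive simple-path
enumeration, shortest paths by Floyd–Warshall on a dense matrix, k-hop
reachability by a hand-rolled breadth-first search.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np


def betweenness_by_enumeration(net: nx.Graph) -> dict:
    """Brandes-convention betweenness by enumerating all simple paths."""
    nodes = list(net.nodes)
    credit = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(net, s, t))
        if not paths:
            continue
        d = min(len(p) for p in paths) - 1
        shortest = [p for p in paths if len(p) - 1 == d]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            credit[v] += through / len(shortest)
    return credit


def floyd_warshall_lengths(net: nx.Graph) -> np.ndarray:
    """All-pairs shortest hop counts by the classic triple loop."""
    nodes = list(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in net.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def khop_by_bfs(net: nx.Graph, k: int) -> np.ndarray:
    """Reachability within k hops by per-source breadth-first search."""
    nodes = list(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    reach = np.zeros((n, n), dtype=bool)
    for s in nodes:
        depth = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            if depth[u] == k:
                continue
            for w in net.neighbors(u):
                if w not in depth:
                    depth[w] = depth[u] + 1
                    queue.append(w)
        for v, d in depth.items():
            if v != s and d <= k:
                reach[idx[s], idx[v]] = True
    return reach


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi graph over string-labelled nodes."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    labels = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(labels)
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < p:
            g.add_edge(labels[i], labels[j])
    return g


def modularity_by_formula(net: nx.Graph, partition: dict) -> float:
    """Q = sum_c [e_c/m - (d_c/2m)^2] computed directly from the formula."""
    m = net.number_of_edges()
    comms = set(partition.values())
    q = 0.0
    for c in comms:
        members = {v for v, cc in partition.items() if cc == c}
        e_c = sum(1 for u, v in net.edges if u in members and v in members)
        d_c = sum(net.degree(v) for v in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q
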