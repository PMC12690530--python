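"""Cytokine correlation networks and their graph-theoretic characterization.

A per-group Pearson correlation matrix is thresholded at |r| > 0.7 into an
undirected, unweighted graph whose nodes are cytokines.  The module then
computes the measures used to compare inflammatory architectures across
models: eigenvector and betweenness centrality, hub ranking, average
shortest finite path length, Louvain community structure and modularity,
k-hop reachability, Jaccard similarity between reachability matrices, and a
seeded force-directed layout export.

Edges are unweighted for all metrics; the underlying correlation is kept as
an edge attribute only, and a negative r beyond the threshold still forms
an edge (the criterion is |r|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .screen import cytokine_columns

__all__ = [
    "CorrelationMatrix",
    "CommunityPartition",
    "ReachabilityMatrix",
    "NetworkComparison",
    "correlation_matrix",
    "threshold_network",
    "centralities",
    "rank_hubs",
    "average_path_length",
    "louvain_communities",
    "khop_reachability",
    "jaccard_similarity",
    "layout_export",
]

MIN_COMPLETE_PAIRS = 3


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix with per-pair complete-observation counts.

    Undefined correlations (constant cytokine, fewer than
    ``MIN_COMPLETE_PAIRS`` complete observations) are NaN and never create
    edges downstream.
    """

    r: pd.DataFrame
    counts: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)


@dataclass(frozen=True)
class CommunityPartition:
    """Louvain node partition with its Newman–Girvan modularity."""

    communities: Mapping[str, int]
    q: float


@dataclass(frozen=True)
class ReachabilityMatrix:
    """Binary node×node matrix: 1 iff a path of <= k hops joins the pair."""

    labels: list[str]
    matrix: np.ndarray
    k: int

    def pairs(self) -> set[frozenset]:
        """Unordered reachable pairs as label sets."""
        i, j = np.nonzero(np.triu(self.matrix, 1))
        return {frozenset((self.labels[a], self.labels[b])) for a, b in zip(i, j)}


@dataclass(frozen=True)
class NetworkComparison:
    """Jaccard similarity of two reachability relations at one k."""

    jaccard: float
    k: int
    labels: list[str]  # label-union alignment used
    n_both: int
    n_either: int


def correlation_matrix(panel: pd.DataFrame, group: str) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations within one experimental group.

    Rows are the collapsed (one per animal) panel rows of ``group``; pairs
    with fewer than 3 complete observations, and pairs involving a constant
    cytokine, get NaN.  The diagonal is 1 by definition.
    """
    rows = panel[panel["group"] == group]
    if rows.empty:
        raise ValueError(f"group {group!r} absent from panel")
    if len(rows) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 animals")
    values = rows[cytokine_columns(panel)].astype(float)
    r = values.corr(method="pearson", min_periods=MIN_COMPLETE_PAIRS)
    notna = values.notna().astype(int)
    counts = notna.T @ notna
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, counts=counts)


def threshold_network(corr: CorrelationMatrix, tau: float = 0.7) -> nx.Graph:
    """Binarize a correlation matrix into an undirected cytokine graph.

    Edge (i, j) exists iff |r_ij| > tau (strict); NaN correlations never
    create edges; isolated nodes stay in the node set.  The correlation is
    stored as edge attribute ``r``.
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    g = nx.Graph()
    labels = corr.labels
    g.add_nodes_from(labels)
    rmat = corr.r.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rij = rmat[i, j]
            if np.isfinite(rij) and abs(rij) > tau:
                g.add_edge(labels[i], labels[j], r=float(rij))
    return g


def _eigenvector_power(net: nx.Graph, tol: float = 1e-10,
                       max_iter: int = 10_000) -> dict[str, float]:
    # Power iteration on A + I (the shift avoids sign oscillation on
    # bipartite components while preserving eigenvectors).  On disconnected
    # graphs this converges to the dominant eigenvector of the full
    # adjacency; components not carrying the dominant eigenvalue decay to ~0.
    nodes = list(net.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(net, nodelist=nodes)
    if net.number_of_edges() == 0:
        # zero matrix: every vector is an eigenvector; report uniform
        return dict(zip(nodes, np.full(n, 1.0 / np.sqrt(n))))
    v = np.full(n, 1.0 / np.sqrt(n))
    shifted = a + np.eye(n)
    for _ in range(max_iter):
        w = shifted @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return dict(zip(nodes, v))


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Eigenvector and betweenness centrality per node.

    Eigenvector centrality is the dominant eigenvector of the 0/1
    adjacency, non-negative and L2-normalized, from power iteration
    (tolerance 1e-10).  Betweenness follows the Brandes convention:
    fractional credit over tied shortest paths, summed over unordered
    pairs, unnormalized.  Returned as a DataFrame indexed by node with
    columns ``eigenvector, betweenness``.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    eig = _eigenvector_power(net)
    btw = nx.betweenness_centrality(net, normalized=False)
    nodes = list(net.nodes)
    return pd.DataFrame(
        {
            "eigenvector": [eig[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
        },
        index=pd.Index(nodes, name="cytokine"),
    )


def rank_hubs(
    tables: Mapping[str, pd.DataFrame], top_k: int = 5
) -> dict[str, dict[str, object]]:
    """Top-ranked hub cytokines per model, with shared and unique sets.

    ``tables`` maps model name to its centrality table.  For each metric
    the top ``top_k`` nodes per model are taken with a deterministic
    tie-break (value descending, then name ascending); ``shared`` is their
    intersection across all models and ``unique[model]`` the nodes in that
    model's top set only.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    metrics = ("eigenvector", "betweenness")
    out: dict[str, dict[str, object]] = {}
    for metric in metrics:
        tops = {}
        for model, table in tables.items():
            order = sorted(
                table.index, key=lambda v: (-table.loc[v, metric], v)
            )
            tops[model] = order[:top_k]
        shared = set.intersection(*(set(t) for t in tops.values()))
        unique = {
            model: sorted(
                set(tops[model])
                - set.union(
                    set(), *(set(t) for m, t in tops.items() if m != model)
                )
            )
            for model in tops
        }
        out[metric] = {
            "top": tops,
            "shared": sorted(shared),
            "unique": unique,
        }
    return out


def average_path_length(net: nx.Graph) -> float:
    """Mean shortest-path hop count over finite unordered node pairs.

    Pairs in different components are excluded from both numerator and
    denominator; an edgeless graph (no finite pair) is an error.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    total = 0
    n_pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            if target != source:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no finite pairs (edgeless graph)")
    return total / n_pairs  # each unordered pair counted twice; ratio unchanged


def louvain_communities(net: nx.Graph, seed: int) -> CommunityPartition:
    """Louvain partition (resolution 1) and its modularity Q.

    Q = sum_c [e_c/m - (d_c/2m)^2] with m the edge count, e_c the
    intra-community edges and d_c the community degree sum.  The node visit
    order is seeded, making the partition reproducible.
    """
    if net.number_of_edges() == 0:
        raise ValueError("edgeless graph has no community structure")
    comms = nx.community.louvain_communities(net, resolution=1.0, seed=seed)
    q = nx.community.modularity(net, comms, resolution=1.0)
    membership = {v: i for i, c in enumerate(comms) for v in c}
    return CommunityPartition(communities=membership, q=float(q))


def khop_reachability(net: nx.Graph, k: int) -> ReachabilityMatrix:
    """Binary reachability within k hops, via boolean adjacency powers.

    Entry (i, j) is 1 iff the shortest path between distinct nodes i and j
    has length <= k; the diagonal is 0.  (Equivalent to a breadth-first
    search truncated at depth k; the test suite checks the two routes
    agree.)
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = list(net.nodes)
    a = nx.to_numpy_array(net, nodelist=labels).astype(bool)
    reach = a.copy()
    power = a.copy()
    for _ in range(k - 1):
        power = (power.astype(np.uint8) @ a.astype(np.uint8)) > 0
        reach |= power
    np.fill_diagonal(reach, False)
    return ReachabilityMatrix(labels=labels, matrix=reach, k=k)


def jaccard_similarity(
    a: ReachabilityMatrix, b: ReachabilityMatrix
) -> NetworkComparison:
    """Jaccard index between two reachability relations at the same k.

    Node sets are aligned by label union (a node absent from one network
    contributes all-zero rows there); J = |both| / |either| over unordered
    off-diagonal pairs.  Two all-zero relations over identical node sets
    are identical empty relations, defined as J = 1; an empty union with
    differing node sets gives J = 0.
    """
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} != {b.k}")
    pairs_a = a.pairs()
    pairs_b = b.pairs()
    union = pairs_a | pairs_b
    labels = sorted(set(a.labels) | set(b.labels))
    if not union:
        j = 1.0 if set(a.labels) == set(b.labels) else 0.0
        return NetworkComparison(j, a.k, labels, 0, 0)
    both = pairs_a & pairs_b
    return NetworkComparison(
        jaccard=len(both) / len(union),
        k=a.k,
        labels=labels,
        n_both=len(both),
        n_either=len(union),
    )


def layout_export(
    net: nx.Graph, centrality_table: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded force-directed layout plus styling columns for plotting.

    Returns a node table (``cytokine, x, y, color_value, size_value`` —
    color from eigenvector centrality, size from betweenness) and an edge
    table (``source, target, r``), both consumable by any plotting tool.
    """
    if set(net.nodes) != set(centrality_table.index):
        raise ValueError("centrality table does not match network nodes")
    pos = nx.spring_layout(net, seed=seed)
    nodes = pd.DataFrame(
        {
            "cytokine": list(net.nodes),
            "x": [pos[v][0] for v in net.nodes],
            "y": [pos[v][1] for v in net.nodes],
            "color_value": [
                centrality_table.loc[v, "eigenvector"] for v in net.nodes
            ],
            "size_value": [
                centrality_table.loc[v, "betweenness"] for v in net.nodes
            ],
        }
    )
    edges = pd.DataFrame(
        [(u, v, d.get("r", np.nan)) for u, v, d in net.edges(data=True)],
        columns=["source", "target", "r"],
    )
    return nodes, edges
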