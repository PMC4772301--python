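"""Markov Cluster (MCL) algorithm on weighted similarity graphs.

MCL simulates flow on a graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power, spreading flow) and *inflated*
(elementwise power followed by column renormalisation, strengthening
strong currents and weakening weak ones) until the flow matrix reaches a
near-idempotent attractor state. Clusters are read off from the attractor
structure. The inflation exponent controls granularity: larger values give
finer clusterings.

This implementation is dense (numpy) with entry pruning; the graphs in
this pipeline (domain families, homology groups) are at most a few
thousand nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class MclParams:
    """MCL tuning parameters.

    inflation
        Elementwise power applied each iteration; must exceed 1. The
        canonical default is 2.0; the metatranscriptome homology grouping
        uses 3.6.
    expansion
        Matrix-power exponent (>= 2); 2 is standard.
    prune_threshold
        Entries below this are zeroed after each iteration (with a guard
        that never empties a column).
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.prune_threshold < 0 or self.max_iterations < 1:
            raise ValueError("invalid pruning/iteration parameters")


@dataclass
class Clustering:
    """A partition of graph nodes; clusters sorted by size then member id."""

    clusters: list[tuple[Hashable, ...]]
    converged: bool = True

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (tuple(sorted(c, key=str)) for c in self.clusters),
            key=lambda c: (-len(c), str(c[0])),
        )
        members = [m for c in self.clusters for m in c]
        if len(members) != len(set(members)):
            raise ValueError("clusters are not disjoint")

    def membership(self) -> dict[Hashable, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def _validate_graph(graph: nx.Graph) -> None:
    if graph.is_directed():
        raise ValueError("similarity graph must be undirected (symmetric)")
    for u, v, w in graph.edges(data="weight", default=1.0):
        if w < 0:
            raise ValueError(f"negative edge weight on ({u!r}, {v!r})")


def mcl_cluster(graph: nx.Graph, params: MclParams | None = None) -> Clustering:
    """Cluster an undirected non-negatively weighted graph with MCL.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes) before column normalisation. After
    convergence, attractors are the nodes with positive return flow
    (diagonal entries); attractors that exchange flow form one attractor
    system, and every other node joins the system of its
    largest-probability attractor (ties broken by smallest node id).

    Deterministic: the iteration involves no randomness.
    """
    if params is None:
        params = MclParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    _validate_graph(graph)

    nodes = sorted(graph.nodes(), key=str)
    n = len(nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(A, 0.0)
    loops = A.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(A, loops)

    M = A / A.sum(axis=0)

    converged = False
    for _ in range(params.max_iterations):
        M_next = np.linalg.matrix_power(M, params.expansion)
        np.power(M_next, params.inflation, out=M_next)
        M_next /= M_next.sum(axis=0)
        # prune small entries, but never empty a column
        keep = M_next >= params.prune_threshold
        keep[M_next.argmax(axis=0), np.arange(n)] = True
        M_next *= keep
        M_next /= M_next.sum(axis=0)
        change = np.abs(M_next - M).max()
        M = M_next
        if change < params.convergence_tolerance:
            converged = True
            break

    eps = max(params.prune_threshold, 1e-9)
    attractors = np.flatnonzero(np.diag(M) > eps)

    # attractor systems: attractors exchanging flow share a cluster
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    att_set = set(int(i) for i in attractors)
    for i in att_set:
        for j in att_set:
            if i < j and (M[i, j] > eps or M[j, i] > eps):
                union(i, j)

    cluster_of: dict[int, set[int]] = {}
    assignments: dict[int, int] = {}
    for i in att_set:
        root = find(i)
        cluster_of.setdefault(root, set()).add(i)
        assignments[i] = root

    for j in range(n):
        if j in assignments:
            continue
        col = M[:, j]
        best, best_p = None, 0.0
        for i in att_set:
            if col[i] > best_p or (col[i] == best_p and best is not None and i < best and col[i] > 0):
                best, best_p = i, col[i]
        if best is None:
            # no flow towards any attractor (non-converged pathology)
            cluster_of.setdefault(-j - 1, set()).add(j)
            assignments[j] = -j - 1
        else:
            root = find(best)
            cluster_of[root].add(j)
            assignments[j] = root

    clusters = [tuple(nodes[i] for i in sorted(c)) for c in cluster_of.values()]
    return Clustering(clusters=clusters, converged=converged)


def connected_components(graph: nx.Graph) -> Clustering:
    """Weakly-connected components as a Clustering (MCL limit oracle)."""
    g = graph.to_undirected() if graph.is_directed() else graph
    return Clustering(clusters=[tuple(c) for c in nx.connected_components(g)])


def graph_from_edges(
    edges: Sequence[tuple[Hashable, Hashable, float]],
    nodes: Sequence[Hashable] = (),
) -> nx.Graph:
    """Build a similarity graph from a (u, v, weight) edge list."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        if w < 0:
            raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
        g.add_edge(u, v, weight=float(w))
    return g


def read_abc(path) -> nx.Graph:
    """Read a 3-column whitespace-separated weighted edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, w = line.split()[:3]
            edges.append((u, v, float(w)))
    return graph_from_edges(edges)


def write_clusters(clustering: Clustering, path) -> None:
    """Write one cluster per line, tab-separated member ids (mcl dump style)."""
    with open(path, "w") as fh:
        for cluster in clustering:
            fh.write("\t".join(str(m) for m in cluster) + "\n")
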