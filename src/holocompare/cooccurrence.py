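"""Per-species domain co-occurrence networks.

Nodes are protein domains; an edge between two domains carries, for each
species, the number of proteins of that species containing at least one
occurrence of both domains (presence-based, not occurrence-count-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .io_formats import ProteinDomainTable


@dataclass
class CooccurrenceGraph:
    """Undirected domain graph with per-species edge weights.

    Edge attribute ``weights`` maps species id -> co-occurrence count.
    ``node_size`` (number of incident edges) reflects the current edge set.
    """

    graph: nx.Graph
    species: tuple[str, ...]

    def weight(self, d1: str, d2: str, species: str) -> int:
        if not self.graph.has_edge(d1, d2):
            return 0
        return self.graph.edges[d1, d2]["weights"].get(species, 0)

    def node_size(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edges(self):
        return self.graph.edges(data="weights")


def build_cooccurrence(
    tables: Iterable[ProteinDomainTable],
    domain_subset: Iterable[str],
) -> CooccurrenceGraph:
    """Count, per species, proteins in which each unordered domain pair co-occurs.

    Every protein contributes exactly 1 to an edge for each unordered pair
    of *distinct* subset domains it contains, however many copies of each
    it carries. Self-pairs are excluded.
    """
    subset = set(domain_subset)
    tables = list(tables)
    g = nx.Graph()
    species_ids = tuple(t.species_id for t in tables)
    for t in tables:
        per_protein: dict[str, set[str]] = {}
        for rec in t.records:
            if rec.domain_id in subset:
                per_protein.setdefault(rec.protein_id, set()).add(rec.domain_id)
        for domains in per_protein.values():
            for d1, d2 in combinations(sorted(domains), 2):
                if not g.has_edge(d1, d2):
                    g.add_edge(d1, d2, weights={})
                w = g.edges[d1, d2]["weights"]
                w[t.species_id] = w.get(t.species_id, 0) + 1
    return CooccurrenceGraph(graph=g, species=species_ids)


def filter_edges(
    coocc: CooccurrenceGraph,
    min_count: int = 5,
    min_species: int = 1,
) -> CooccurrenceGraph:
    """Keep an edge iff its weight reaches min_count in at least min_species
    species; drop nodes left isolated."""
    if min_count < 1 or min_species < 1:
        raise ValueError("min_count and min_species must be >= 1")
    g = nx.Graph()
    for d1, d2, weights in coocc.graph.edges(data="weights"):
        n_ok = sum(1 for w in weights.values() if w >= min_count)
        if n_ok >= min_species:
            g.add_edge(d1, d2, weights=dict(weights))
    return CooccurrenceGraph(graph=g, species=coocc.species)


def write_edge_tsv(coocc: CooccurrenceGraph, path, retained: CooccurrenceGraph | None = None) -> None:
    """Write the edge list with per-species weights and a retained flag."""
    with open(path, "w") as fh:
        fh.write("domain1\tdomain2\t" + "\t".join(coocc.species) + "\tretained\n")
        for d1, d2, weights in sorted(coocc.graph.edges(data="weights")):
            flag = (
                "1"
                if retained is None or retained.graph.has_edge(d1, d2)
                else "0"
            )
            cols = [str(weights.get(s, 0)) for s in coocc.species]
            fh.write(f"{d1}\t{d2}\t" + "\t".join(cols) + f"\t{flag}\n")


def write_graphml(coocc: CooccurrenceGraph, path) -> None:
    """GraphML export (per-species weights flattened into edge attributes)."""
    g = nx.Graph()
    g.add_nodes_from(coocc.graph.nodes())
    for d1, d2, weights in coocc.graph.edges(data="weights"):
        attrs = {f"w_{s}": int(w) for s, w in weights.items()}
        g.add_edge(d1, d2, **attrs)
    nx.write_graphml(g, path)
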