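"""Bipartite gene ↔ gene-set network export.

For a selection of enriched gene sets, the network has one node per
selected set and one node per input gene overlapping at least one of
them; an edge joins a set to each of its overlapping input genes.  Genes
shared by several selected sets get several edges, which is what makes
the view useful: it shows which genes tie the enriched categories
together and which are private to one.  Sets with no overlapping input
gene are omitted (no orphan nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .enrich import EnrichmentResult
from .errors import SetNotFoundError
from .idmap import MappedList


@dataclass(frozen=True)
class BipartiteGraph:
    """Nodes are (id, kind, label) with kind in {gene, gene_set}; edges are
    (gene_set_id, gene_id) membership pairs."""

    nodes: tuple[tuple[str, str, str], ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def gene_nodes(self) -> tuple[str, ...]:
        return tuple(n[0] for n in self.nodes if n[1] == "gene")

    @property
    def set_nodes(self) -> tuple[str, ...]:
        return tuple(n[0] for n in self.nodes if n[1] == "gene_set")


def build_graph(
    results: Sequence[EnrichmentResult],
    selected_set_ids: Iterable[str],
    gene_list: MappedList | Iterable[str] | None = None,
) -> BipartiteGraph:
    """Build the bipartite graph for a selection of result sets.

    Edges come from each result's overlap members (input ∩ set), so every
    edge's gene is both a set member and an input gene by construction;
    ``gene_list`` optionally restricts genes further.  Unknown selected
    ids raise :class:`SetNotFoundError`.
    """
    by_id = {r.set_id: r for r in results}
    if gene_list is None:
        allowed = None
    elif isinstance(gene_list, MappedList):
        allowed = gene_list.genes
    else:
        allowed = frozenset(gene_list)

    nodes: list[tuple[str, str, str]] = []
    edges: list[tuple[str, str]] = []
    genes: set[str] = set()
    for set_id in sorted(set(selected_set_ids)):
        if set_id not in by_id:
            raise SetNotFoundError(set_id)
        r = by_id[set_id]
        overlap = [g for g in r.overlap_members if allowed is None or g in allowed]
        if not overlap:
            continue  # k=0 selections yield no node
        nodes.append((set_id, "gene_set", r.name))
        for g in overlap:
            edges.append((set_id, g))
            genes.add(g)
    nodes.extend((g, "gene", g) for g in sorted(genes))
    return BipartiteGraph(nodes=tuple(nodes), edges=tuple(sorted(edges)))


def to_networkx(graph: BipartiteGraph) -> nx.Graph:
    """Convert to a networkx graph with kind/label node attributes."""
    g = nx.Graph()
    for node_id, kind, label in graph.nodes:
        g.add_node(node_id, kind=kind, label=label,
                   bipartite=0 if kind == "gene_set" else 1)
    g.add_edges_from(graph.edges)
    return g


def write_graphml(graph: BipartiteGraph, path: str | Path) -> None:
    """Write GraphML (deterministic node/edge order)."""
    nx.write_graphml(to_networkx(graph), str(path))


def write_node_edge_tsv(
    graph: BipartiteGraph, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Write node and edge tables as TSV."""
    node_lines = ["id\tkind\tlabel"]
    node_lines += [f"{i}\t{k}\t{l}" for i, k, l in graph.nodes]
    Path(nodes_path).write_text("\n".join(node_lines) + "\n")
    edge_lines = ["gene_set_id\tgene_id"]
    edge_lines += [f"{s}\t{g}" for s, g in graph.edges]
    Path(edges_path).write_text("\n".join(edge_lines) + "\n")
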