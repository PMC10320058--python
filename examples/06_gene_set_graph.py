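"""Export the bipartite gene <-> gene-set network for selected sets.

After enrichment, selected sets and their overlapping input genes form a
bipartite graph whose edges are memberships — useful for spotting genes
shared between enriched categories.
"""

from oraset import GeneSet, GeneSetCollection, build_graph, run_enrichment
from oraset.graphs import to_networkx

collection = GeneSetCollection("demo", gene_sets=[
    GeneSet("S1", "mRNA metabolism", "slim", frozenset({"g1", "g2"})),
    GeneSet("S2", "protein folding", "slim", frozenset({"g2", "g3"})),
    GeneSet("S3", "unrelated", "slim", frozenset({"g9"})),
])

results, _ = run_enrichment(["g1", "g2", "g3"], collection)
graph = build_graph(results, ["S1", "S2", "S3"])

print(f"set nodes : {graph.set_nodes}")
print(f"gene nodes: {graph.gene_nodes}")
print("edges:")
for set_id, gene_id in graph.edges:
    print(f"  {set_id} -- {gene_id}")

nxg = to_networkx(graph)
print(f"\ndegree of g2: {nxg.degree['g2']}")

print("""
g2 sits in both selected sets, so it carries two edges and links the two
categories; S3 overlaps no input gene and is omitted entirely (no orphan
nodes).  The same graph can be written as GraphML or node/edge TSVs for
network viewers.""")
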