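"""Hypergeometric over-representation test of one gene list.

A 10-gene universe contains a 5-gene marked set; the input list is 4 genes,
all inside the marked set.  Prints the 2x2 counts, raw and adjusted
p-values, and fold enrichment.
"""

from oraset import GeneSet, GeneSetCollection, run_enrichment

genes = [f"g{i}" for i in range(1, 11)]
collection = GeneSetCollection("demo", gene_sets=[
    GeneSet("S1", "marked pathway", "pathway", frozenset(genes[:5])),
    GeneSet("ALL", "whole universe", "pathway", frozenset(genes)),
])

results, uncovered = run_enrichment(["g1", "g2", "g3", "g4"], collection)
print("set_id  N   K  n  k  p_raw     p_bh      fold")
for r in results:
    print(f"{r.set_id:6} {r.N:3} {r.K:2} {r.n:2} {r.k:2}  "
          f"{r.p_raw:.6f}  {r.p_adj['bh']:.6f}  {r.fold_enrichment:.2f}")
print(f"uncovered genes: {list(uncovered.genes)} "
      f"(fraction {uncovered.fraction:.2f})")

print("""
S1's p = P(X >= 4) for X ~ Hypergeom(N=10, K=5, n=4) = 5/210 ~ 0.0238:
drawing 4 genes at random, fewer than 1 in 40 draws land entirely inside
the marked set.  Fold enrichment (k/n)/(K/N) = (4/4)/(5/10) = 2: the list
overlaps the set twice as much as expected by chance.  ALL overlaps every
draw fully, so its p is 1 (no over-representation).""")
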