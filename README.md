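# oraset

Configurable gene-set over-representation analysis for model-organism
gene lists.

`omics` experiments — RNAi screens, proteomics pull-downs, differential
expression — end in a gene list, and the first question is always the
same: which biological features are over-represented in it?  `oraset` is
a library (plus a thin CLI) for answering that question against
*configurable* gene-set collections, the way model-organism researchers
need to: Gene Ontology annotation sets built with or without ancestor
propagation, restricted to experimental evidence or purged of
high-throughput-only support, re-expressed on GO slims; pathway, complex
and gene-group sets from GMT files; phenotype sets derived from
genotype–phenotype tables under a strict single-allele rule; and
tissue-preferential expression sets classified from RPKM matrices.  It
also handles the unglamorous parts that make or break an analysis:
identifier synchronisation, explicit background (universe) control,
uncovered-gene reporting, side-by-side comparison of multiple lists, and
bipartite gene ↔ gene-set network export.

## The statistic

For an input list and one gene set, restricted to a background of `N`
genes containing `K` set members, with `n` input genes of which `k` fall
in the set, the over-representation p-value is the hypergeometric upper
tail

```
P(X ≥ k) = Σ_{j=k}^{min(n,K)}  C(K,j) · C(N−K, n−j) / C(N,n)
```

computed one-sided (over-representation only) via the log-space survival
function.  All sets tested in one call form the multiple-testing family,
over which three adjustments are computed: Bonferroni (`min(1, p·m)`),
Benjamini–Hochberg step-up FDR, and Benjamini–Yekutieli
(BH scaled by `c(m) = Σ_{i=1..m} 1/i`, valid under arbitrary
dependence).  Fold enrichment is `(k/n)/(K/N)`.  The default background
is the collection universe — every gene annotated in the selected
category — and a user-supplied background is intersected with it, with
the discarded count reported.

## Worked example

```python
from oraset import GeneSet, GeneSetCollection, run_enrichment

genes = [f"g{i}" for i in range(1, 11)]
collection = GeneSetCollection("demo", gene_sets=[
    GeneSet("S1", "marked pathway", "pathway", frozenset(genes[:5])),
    GeneSet("ALL", "whole universe", "pathway", frozenset(genes)),
])
results, uncovered = run_enrichment(["g1", "g2", "g3", "g4"], collection)
for r in results:
    print(r.set_id, (r.N, r.K, r.n, r.k), round(r.p_raw, 6), r.fold_enrichment)
```

prints

```
S1 (10, 5, 4, 4) 0.02381 2.0
ALL (10, 10, 4, 4) 1.0 1.0
```

A 4-gene list drawn entirely from a 5-gene set in a 10-gene universe has
p = 5/210 ≈ 0.0238 — fewer than 1 in 40 random draws overlap that well —
and fold enrichment (4/4)/(5/10) = 2.  The `ALL` set covers every draw,
so its p is 1.  `examples/` contains one short script per capability
(collection building, single-list and multi-list enrichment, tissue
classification, identifier mapping, graph export), each printing the
numbers it computes and what they mean.

## Command line

The same pipeline is exposed as `oraset` subcommands that compose via
files:

```
oraset fixtures --seed 1 --out-dir fx          # synthetic inputs + ground truth
oraset build-sets --gaf fx/annotations.gaf --obo fx/ontology.obo --out go.gmt
oraset enrich fx/toy_list.txt --collection fx/toy_sets.gmt --out results.tsv
oraset enrich-multi fx/list_*.txt --collection fx/pathways.gmt --out-dir multi/
oraset graph-export --results results.tsv --sets TOY:S1 --out-prefix graph
oraset plot --matrix multi/comparison_matrix.tsv --kind heatmap --out hm.json
```

Exit codes: 0 success, 1 data error, 2 usage error.

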