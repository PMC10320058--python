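# Methods

This note documents the models, rules and numerical choices behind
`oraset`, the assumptions they rest on, and what the synthetic fixtures
do and do not demonstrate.

## Ontology handling and "flattening"

Ontologies (GO and similar controlled vocabularies) are parsed from OBO
1.2/1.4 flat files into a DAG of terms.  Propagation — extending a
gene's annotation from a term to its ancestors, also called flattening —
traverses `is_a` and `part_of` links only.  This is the standard,
conservative choice for GO set construction: `regulates`-type links
change the meaning of membership (a regulator of a process is not part
of it), so they are ignored.  `part_of` links that cross namespaces are
not followed either, because enrichment categories are per aspect
(biological process / molecular function / cellular component) and
cross-aspect propagation would leak genes between categories.

Obsolete terms are retained in the parsed ontology (so files load
faithfully) but excluded from propagation and set construction;
annotations to them are skipped with a warning and counted in the
collection's provenance rather than remapped, because `replaced_by`
policies differ between releases and silent remapping is not
reproducible.  Alternate ids resolve silently to their primary term.
Cycles are a hard load error: every downstream guarantee assumes a DAG.

Slim mapping uses propagate-then-intersect semantics: a term maps to
every slim term in its ancestor closure (including itself), possibly
none.  The alternative — nearest slim ancestor only — under-counts
membership for slims whose terms are nested, and does not correspond to
how slim annotation sets are used for coarse classification.

## Annotation sets and evidence filtering

GAF 2.1/2.2 rows become one annotation record each; records carrying a
`NOT` qualifier are removed before any set construction (they assert
non-membership).  Evidence filtering operates at the (gene, term) *pair*
level: a pair is dropped only when **every** supporting annotation
carries an excluded code.  The `experimental_only` subset excludes pairs
supported solely by computational codes (IEA, IBA, IBD, IKR, IRD, ISS,
ISO, ISA, ISM, IGC, RCA); the `exclude_htp_only` subset excludes pairs
supported solely by high-throughput codes (HTP, HDA, HMP, HGI, HEP) —
useful to avoid circularity when the list being analysed itself comes
from a high-throughput study.  One non-excluded code rescues the pair,
and a rescued pair keeps all of its records.

Phenotype sets apply the single-allele rule: a genotype contributes a
gene → phenotype link only when exactly one gene is implicated *and* the
allele class is classical or insertional.  Multi-gene genotypes and
other allele classes (transgenic constructs, aberrations) are excluded
because the phenotype cannot be attributed to one gene's perturbation.
Which allele classes count as classical/insertional is externalised to
the `allele_class` column of the input table, since that judgment
depends on the curation source.  If a phenotype-vocabulary ontology is
supplied, membership propagates to ancestor terms exactly as for GO.

Empty sets are dropped from every collection: they cannot be enriched
and would inflate the multiple-testing family.

## Identifier mapping

Lookup is exact-match first, case-insensitive fallback second.  The
fallback is deliberately cautious: any case-insensitive hit reaching
more than one canonical id is reported ambiguous, never folded — fly
symbols are case-meaningful (`dl`/dorsal vs `Dl`/Delta), and silent
case-folding corrupts fly lists.  Ambiguous tokens are excluded from the
mapped output by default because adding uncertain members inflates `k`
and biases enrichment upward; `include_ambiguous` adds all candidates,
flagged.  Every input token lands in exactly one of mapped / unmapped /
ambiguous / duplicate, so the partition identity
`|input| = mapped + unmapped + ambiguous + duplicates` always holds, and
mapping is idempotent (canonical ids self-alias).  Secondary and retired
ids are ordinary alias rows; there is no release-reconciliation logic.

## The enrichment test

One-sided upper-tail hypergeometric only: the tool reports
over-representation, not depletion.  The p-value is computed with the
log-space survival function (`scipy.stats.hypergeom.sf(k-1, N, K, n)`),
clamped into (0, 1]; exhaustive-enumeration tests confirm agreement to
~1e-16 over all parameter combinations with N ≤ 12, and the survival
function remains finite and positive at genome scale (N ~ 15 000).

Defaults and family definition, all configurable and all flagged here
because different tools choose differently:

- **Background** defaults to the collection universe (all genes
  annotated in the selected category).  A user-supplied background is
  intersected with the universe first — genes the collection knows
  nothing about cannot inform the test — and the discarded count is
  reported.
- **The multiple-testing family** is the sets tested within one
  (list × collection) call, after the `min_set_size` filter
  (default 1 = no filtering).  Per-call families are reproducible and
  independent of what else a user analyses.
- **Zero-overlap sets are reported** (p = 1) unless a cutoff removes
  them, so multi-list matrices stay dense.
- **Ordering** is by raw p ascending with `set_id` as tie-break, making
  output byte-stable.

Adjustments are computed in-package (Bonferroni; BH step-up with
monotonicity enforced by a running minimum from the largest p; BY = BH
scaled by `c(m) = Σ 1/i` before capping at 1) and are verified
elementwise against statsmodels' `multipletests` in the test suite.  One
caveat worth stating: BY is *not* pointwise below Bonferroni.  For the
smallest-rank p-values BY ≈ p·m·c(m)/i exceeds p·m whenever c(m) > i, a
property shared by the R `p.adjust` reference semantics; the orderings
that do hold universally are raw ≤ BH ≤ BY and BH ≤ Bonferroni, and
those are what the tests assert.

The uncovered report lists input genes (within the background) that
belong to no set of the selected collection, regardless of
`min_set_size` — often the most interesting genes, being the least
characterised.

## Tissue-preferential expression

Samples are grouped by tissue; per-group means are unweighted arithmetic
means over samples (no re-weighting by dataset of origin).  A gene is
assigned to group G iff `mean(g,G) ≥ min_rpkm` (default 10) and
`mean(g,G) ≥ fold_threshold · mean(g,G′)` (default 3) for every other
group G′.  Both comparisons are inclusive (`≥`), reading "3-fold or
higher" and "lower than 10 ... excluded" literally.  The RPKM floor is
applied to the candidate group's mean — the local reading; applying it
to the global mean would let a gene's irrelevant tissues veto its
assignment.  A zero mean elsewhere satisfies the fold condition
automatically (no special-casing of infinite ratios).  With a fold
threshold above 1 the rule can hold in at most one group (mutual
3-fold dominance forces both means to 0, which the floor excludes), so
tissue sets are disjoint by construction; for thresholds ≤ 1 ties are
resolved to the lexicographically first qualifying group.

## Multi-list comparison and graphs

Each list is analysed independently — one adjustment family per list —
because pooling families would make one list's adjusted values depend on
which other lists happen to be analysed alongside it.  The comparison
matrix's rows are the union of sets passing the cutoff in at least one
list; every cell is the exact value from that list's own result table
(no recomputation), and never-tested cells carry an explicit p = 1
marker rather than a blank so exports are dense.  Bar heights and
heatmap/dot-plot colours are −log10(p) with p clamped at 1e-300 to keep
plot coordinates finite; dot sizes are overlap counts `k`.  Graph edges
are unweighted memberships (a gene either is or is not in a set), and
sets with no overlapping input gene are omitted so the graph has no
orphan nodes.  All serialized outputs (TSV, JSON with sorted keys,
GraphML with fixed node order) are byte-deterministic.

## Synthetic fixtures

The fixture generator emulates the knowledgebase sources at desk scale:
a random-DAG ontology (default 20 terms, ≤ 4 layers, ~20% `part_of`
links, one alt_id, one obsolete term), a 17-column GAF over 60 genes
with an evidence-code mix of 60% experimental / 30% computational / 10%
high-throughput plus planted only-IEA, only-HDA and NOT-qualified rows,
five pathway-style GMT sets, an expression matrix (3 tissue groups × 2
replicates) with 5 genes planted to satisfy the 3-fold/≥10 rule in
exactly one group (in-group samples ~U(80, 120), out-of-group
~U(0.5, 3); unplanted genes get ≤ ±10% jitter around a shared base so
their group means can never reach 3-fold), a genotype–phenotype table
covering qualifying and non-qualifying records, an id-mapping table
including reference aliases and a deliberately ambiguous one, and gene
lists with 80% planted overlap of one pathway.  All sampling flows
through a single seeded generator, so identical seeds give byte-identical
files; the ground-truth JSON is computed with independent machinery
(`math.comb` tail sums, iterative set-expansion closures) rather than
the analysis modules it validates.

What passing these tests shows: the algorithms implement their stated
rules exactly, deterministically, at small scale.  What they do not
show: behaviour on real annotation corpora — release inconsistencies,
heavy-tailed set-size distributions, correlated sets, ID churn — or the
statistical power of the test on noisy biological lists.  Runtime scales
were chosen to keep the full suite and the acceptance script in the
minutes range on one CPU: exhaustive hypergeometric enumeration up to
N = 12, 1000 random adjustment vectors of length ≤ 50, 200 random DAGs
of ≤ 50 terms and ≤ 100 genes, and 60-gene fixtures; all are
comfortably beyond the sizes where implementation errors hide.

## Known limitations

- Rank-based GSEA on scored lists (KS/permutation statistics),
  depletion tests and gene-level weighting are out of scope; the test is
  over-representation of an unordered list.
- OWL parsing and reasoner-grade inference are not supported; OBO only.
- No network access anywhere: ontologies, GAFs, GMTs and tables are
  local files, and assembling them from live database releases is the
  caller's concern.
- The static plot renderer is a convenience; the deterministic JSON
  plot-data documents are the primary visualisation interface.
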