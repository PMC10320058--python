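"""Build GO-style gene-set collections: direct vs propagated, evidence filters.

Generates a synthetic ontology + GAF, then builds the annotation
collection four ways and prints how flattening and evidence filtering
change the number of sets and the total annotated universe.
"""

import tempfile
from pathlib import Path

from oraset import EvidenceFilter, FixtureSpec, build_go_sets, generate_fixture, load_obo, read_gaf

with tempfile.TemporaryDirectory() as tmp:
    fx = Path(tmp)
    generate_fixture(FixtureSpec(seed=1), fx)
    ontology = load_obo(fx / "ontology.obo")
    records = read_gaf(fx / "annotations.gaf")

    print(f"{len(ontology)} terms, {len(records)} GAF records\n")
    for propagate in (False, True):
        for mode in ("all", "experimental_only", "exclude_htp_only"):
            coll = build_go_sets(records, ontology, propagate=propagate,
                                 evidence_filter=EvidenceFilter(mode))
            sizes = sorted((len(s.members) for s in coll), reverse=True)
            print(f"propagate={propagate!s:5}  evidence={mode:17}  "
                  f"{len(coll):2d} sets  universe={len(coll.universe):2d}  "
                  f"largest set={sizes[0]}")

print("""
Propagation ("flattening") extends each gene's annotation to all ancestor
terms, so propagated sets are supersets of direct ones and high-level terms
accumulate most genes.  The experimental-only filter drops (gene, term)
pairs supported exclusively by computational codes (IEA, ISS, ...); the
no-HTP filter drops pairs supported only by high-throughput codes.""")
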