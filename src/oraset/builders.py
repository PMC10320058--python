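"""Build gene-set collections from annotations and genotype–phenotype tables.

GO collections come in two flavours: *direct* (gene belongs to exactly the
terms it is annotated to) and *propagated* ("flattened": a gene annotated
to a term also belongs to every ancestor term, reflecting the intended use
of the ontology in curation).  Either can be re-expressed on a slim.

Phenotype collections apply the single-allele rule: a genotype contributes
a gene→phenotype link only when the phenotype can be attributed to the
perturbation of exactly one gene through a single classical or insertional
allele.  Multi-gene genotypes and other allele classes (transgenic
constructs, aberrations, ...) are excluded.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotations import AnnotationRecord, EvidenceFilter, filter_by_evidence
from .errors import ParseError
from .genesets import GeneSet, GeneSetCollection
from .ontology import Ontology, SlimSubset, map_to_slim

logger = logging.getLogger(__name__)

#: allele classes that qualify under the single-allele rule
QUALIFYING_ALLELE_CLASSES = frozenset({"classical", "insertional"})


def build_go_sets(
    records: Sequence[AnnotationRecord],
    ontology: Ontology,
    propagate: bool = True,
    evidence_filter: EvidenceFilter | None = None,
    slim: SlimSubset | None = None,
    aspect: str | None = None,
    collection_id: str | None = None,
    species: str = "",
) -> GeneSetCollection:
    """Assemble a GO gene-set collection from annotation records.

    Parameters
    ----------
    propagate
        If True, membership is extended to all ancestors of each annotated
        term (is_a/part_of closure).  Ignored when ``slim`` is given, since
        slim mapping already includes the ancestor closure.
    evidence_filter
        Pair-level evidence filtering applied before set construction
        (NOT-qualified records are removed in either case).
    slim
        Re-express membership on slim terms via propagate-then-intersect.
    aspect
        Restrict to one GO aspect (P, F or C); None keeps all aspects.

    Records whose term is absent from the ontology, or is obsolete, are
    skipped with a warning and counted in the collection's provenance.
    """
    evidence_filter = evidence_filter or EvidenceFilter("all")
    surviving = filter_by_evidence(records, evidence_filter)
    if aspect is not None:
        surviving = [r for r in surviving if r.aspect == aspect]

    members: dict[str, set[str]] = {}
    skipped_unknown = 0
    skipped_obsolete = 0
    for rec in surviving:
        if rec.term_id not in ontology:
            skipped_unknown += 1
            logger.warning("skipping annotation to unknown term %s", rec.term_id)
            continue
        tid = ontology.resolve(rec.term_id)
        if ontology.terms[tid].is_obsolete:
            skipped_obsolete += 1
            logger.warning("skipping annotation to obsolete term %s", tid)
            continue
        if slim is not None:
            targets = map_to_slim(ontology, tid, slim)
        elif propagate:
            targets = {tid} | ontology.ancestors(tid)
        else:
            targets = {tid}
        for t in targets:
            members.setdefault(t, set()).add(rec.gene_id)

    if slim is not None:
        category = f"GO-slim:{slim.slim_id}"
    else:
        category = "GO-propagated" if propagate else "GO-direct"
    if aspect is not None:
        category += f"-{aspect}"
    cid = collection_id or category
    collection = GeneSetCollection(
        collection_id=cid,
        species=species,
        provenance={
            "source": "GAF",
            "evidence_mode": evidence_filter.mode,
            "propagate": bool(propagate and slim is None),
            "slim": slim.slim_id if slim is not None else None,
            "aspect": aspect,
            "records_in": len(records),
            "records_surviving_filters": len(surviving),
            "skipped_unknown_terms": skipped_unknown,
            "skipped_obsolete_terms": skipped_obsolete,
        },
    )
    for tid in sorted(members):
        if not members[tid]:
            continue  # empty sets are dropped: untestable, distort family size
        name = ontology.terms[tid].name or tid
        collection.add(
            GeneSet(set_id=tid, name=name, category=category,
                    members=frozenset(members[tid]))
        )
    return collection


# -- genotype–phenotype -----------------------------------------------


@dataclass(frozen=True)
class GenotypePhenotypeRecord:
    """One genotype→phenotype association row."""

    genotype: str
    phenotype_term_id: str
    gene_ids: tuple[str, ...]
    allele_class: str  # classical | insertional | other/multi

    @property
    def qualifies(self) -> bool:
        """Single-gene, single classical/insertional allele rule."""
        return len(self.gene_ids) == 1 and self.allele_class in QUALIFYING_ALLELE_CLASSES


_GP_COLUMNS = ("genotype", "gene_ids", "allele_class", "phenotype_term_id")


def read_genotype_phenotype_table(path: str | Path) -> list[GenotypePhenotypeRecord]:
    """Read the genotype–phenotype TSV dialect.

    Columns (header required): genotype, gene_ids ('|'-separated),
    allele_class, phenotype_term_id.
    """
    path = Path(path)
    records: list[GenotypePhenotypeRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_GP_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(
                f"genotype-phenotype table missing columns: {sorted(missing)}", str(path), 1
            )
        for lineno, row in enumerate(reader, start=2):
            genes = tuple(g for g in (row["gene_ids"] or "").split("|") if g)
            if not row["phenotype_term_id"]:
                raise ParseError("empty phenotype_term_id", str(path), lineno)
            records.append(
                GenotypePhenotypeRecord(
                    genotype=row["genotype"],
                    phenotype_term_id=row["phenotype_term_id"],
                    gene_ids=genes,
                    allele_class=row["allele_class"],
                )
            )
    return records


def build_phenotype_sets(
    records: Sequence[GenotypePhenotypeRecord],
    ontology: Ontology | None = None,
    collection_id: str = "phenotype-single-allele",
    species: str = "",
) -> GeneSetCollection:
    """Build phenotype gene sets under the single-allele rule.

    Only records implicating exactly one gene through a classical or
    insertional allele contribute.  If a phenotype-vocabulary ontology is
    supplied, membership is propagated to ancestor terms, mirroring the
    flattened treatment of hierarchical vocabularies; without one, sets
    are keyed by the asserted terms only.  Non-qualifying records are
    counted in the provenance report, never an error.
    """
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_qualifying = 0
    skipped_multi_gene = 0
    skipped_allele_class = 0
    skipped_unknown_terms = 0
    for rec in records:
        if len(rec.gene_ids) != 1:
            skipped_multi_gene += 1
            continue
        if rec.allele_class not in QUALIFYING_ALLELE_CLASSES:
            skipped_allele_class += 1
            continue
        n_qualifying += 1
        gene = rec.gene_ids[0]
        if ontology is not None:
            if rec.phenotype_term_id not in ontology:
                skipped_unknown_terms += 1
                logger.warning("skipping unknown phenotype term %s", rec.phenotype_term_id)
                continue
            tid = ontology.resolve(rec.phenotype_term_id)
            targets = {tid} | ontology.ancestors(tid)
            for t in targets:
                names.setdefault(t, ontology.terms[t].name or t)
        else:
            targets = {rec.phenotype_term_id}
        for t in targets:
            members.setdefault(t, set()).add(gene)

    collection = GeneSetCollection(
        collection_id=collection_id,
        species=species,
        provenance={
            "source": "genotype-phenotype table",
            "records_in": len(records),
            "records_qualifying": n_qualifying,
            "skipped_multi_gene": skipped_multi_gene,
            "skipped_allele_class": skipped_allele_class,
            "skipped_unknown_terms": skipped_unknown_terms,
        },
    )
    for tid in sorted(members):
        collection.add(
            GeneSet(set_id=tid, name=names.get(tid, tid), category="phenotype",
                    members=frozenset(members[tid]))
        )
    return collection
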