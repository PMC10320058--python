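"""GAF annotation records and evidence-code filtering.

GO annotations carry evidence codes describing the support behind each
gene-to-term assertion (IDA = direct assay, IEA = electronic, HDA =
high-throughput direct assay, ...).  Two derived annotation subsets are
supported alongside the full set:

``experimental_only``
    drops a (gene, term) pair when *every* supporting annotation carries a
    computational code (IEA, IBA, IBD, IKR, IRD, ISS, ISO, ISA, ISM, IGC,
    RCA) — i.e. annotations only based on phylogenetic, sequence or
    structural similarity or other computational analyses.
``exclude_htp_only``
    drops a pair when every supporting annotation carries a high-throughput
    code (HTP, HDA, HMP, HGI, HEP).

The "only" semantics operate at the (gene, term) pair level: one
annotation outside the exclusion list keeps the pair, and the pair then
retains all of its records.  NOT-qualified records never contribute to
set membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.UniProt import GOA

from .errors import ConfigurationError, ParseError

#: codes for annotations inferred computationally (similarity, phylogeny, ...)
COMPUTATIONAL_CODES = frozenset(
    {"IEA", "IBA", "IBD", "IKR", "IRD", "ISS", "ISO", "ISA", "ISM", "IGC", "RCA"}
)
#: high-throughput experiment evidence codes
HTP_CODES = frozenset({"HTP", "HDA", "HMP", "HGI", "HEP"})

EVIDENCE_MODES = ("all", "experimental_only", "exclude_htp_only")


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene→term assertion from a GAF row."""

    gene_id: str
    gene_symbol: str
    qualifiers: tuple[str, ...]
    term_id: str
    evidence_code: str
    aspect: str  # P / F / C

    @property
    def is_not(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass(frozen=True)
class EvidenceFilter:
    """Evidence-code filter configuration; code sets are fixed."""

    mode: str = "all"
    computational_codes: frozenset[str] = COMPUTATIONAL_CODES
    htp_codes: frozenset[str] = HTP_CODES

    def __post_init__(self) -> None:
        if self.mode not in EVIDENCE_MODES:
            raise ConfigurationError(
                f"unknown evidence filter mode {self.mode!r}; expected one of {EVIDENCE_MODES}"
            )

    @property
    def excluded_codes(self) -> frozenset[str]:
        if self.mode == "experimental_only":
            return self.computational_codes
        if self.mode == "exclude_htp_only":
            return self.htp_codes
        return frozenset()


_GAF_COLUMNS = 17


def read_gaf(path: str | Path) -> list[AnnotationRecord]:
    """Read a GAF 2.1/2.2 file ('!' comment lines) into annotation records.

    Qualifiers are split on '|'; aspect comes from column 9.  Rows with the
    wrong column count or an empty evidence code raise :class:`ParseError`
    with the offending line number.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            ncol = raw.rstrip("\n").count("\t") + 1
            if ncol != _GAF_COLUMNS:
                raise ParseError(
                    f"expected {_GAF_COLUMNS} tab-separated columns, found {ncol}",
                    str(path),
                    lineno,
                )
            fields = raw.rstrip("\n").split("\t")
            if not fields[6].strip():
                raise ParseError("empty evidence code (column 7)", str(path), lineno)

    records: list[AnnotationRecord] = []
    with open(path) as handle:
        for row in GOA.gafiterator(handle):
            qualifiers = tuple(q for q in row["Qualifier"] if q)
            records.append(
                AnnotationRecord(
                    gene_id=row["DB_Object_ID"],
                    gene_symbol=row["DB_Object_Symbol"],
                    qualifiers=qualifiers,
                    term_id=row["GO_ID"],
                    evidence_code=row["Evidence"],
                    aspect=row["Aspect"],
                )
            )
    return records


def filter_by_evidence(
    records: Sequence[AnnotationRecord], evidence_filter: EvidenceFilter
) -> list[AnnotationRecord]:
    """Apply pair-level evidence filtering; NOT records are always removed.

    A (gene, term) pair is dropped iff every one of its supporting codes
    lies inside the filter's exclusion set; surviving pairs keep all their
    records, in input order.
    """
    positives = [r for r in records if not r.is_not]
    excluded = evidence_filter.excluded_codes
    if not excluded:
        return positives

    codes_by_pair: dict[tuple[str, str], set[str]] = {}
    for r in positives:
        codes_by_pair.setdefault((r.gene_id, r.term_id), set()).add(r.evidence_code)
    dropped = {pair for pair, codes in codes_by_pair.items() if codes <= excluded}
    return [r for r in positives if (r.gene_id, r.term_id) not in dropped]
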