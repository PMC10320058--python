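"""Gene identifier synchronisation.

User lists arrive as a mixture of symbols, Entrez ids, MOD ids and
retired/secondary ids, while gene-set collections are keyed by one
canonical id space (e.g. FlyBase FBgn numbers, HGNC ids).  The mapper
resolves every input token to canonical ids and reports a total partition
of the input: mapped, unmapped, ambiguous, duplicates.

Matching is exact-first.  Case-insensitive matching is a *fallback* only,
and a case-insensitive hit that reaches more than one canonical id (e.g.
fly ``dl`` vs ``Dl``, which are different genes) is reported ambiguous
rather than silently folded.  Ambiguous tokens are excluded from the
mapped output by default, because inflating an input list with uncertain
members biases enrichment upward.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError


class IdMapTable:
    """Alias → canonical-id multi-map with a case-insensitive fallback index.

    Canonical ids always map to themselves (self-aliases are added on
    construction and on every insert).
    """

    def __init__(self, species: str = "", entries: Mapping[str, Iterable[str]] | None = None):
        self.species = species
        self.entries: dict[str, set[str]] = {}
        self.canonical_ids: set[str] = set()
        self._ci_index: dict[str, set[str]] = {}
        if entries:
            for alias, canonicals in entries.items():
                for c in canonicals:
                    self.add(alias, c)

    def add(self, alias: str, canonical_id: str) -> None:
        if not alias or not canonical_id:
            raise ParseError("blank alias or canonical_id")
        for a, c in ((alias, canonical_id), (canonical_id, canonical_id)):
            self.entries.setdefault(a, set()).add(c)
            self._ci_index.setdefault(a.casefold(), set()).add(c)
        self.canonical_ids.add(canonical_id)

    def lookup(self, token: str) -> tuple[frozenset[str], bool]:
        """Return (candidate canonical ids, exact_hit).

        Exact match wins; otherwise all canonical ids reachable through a
        case-insensitive alias match are returned (possibly several — the
        caller decides how to treat ambiguity).
        """
        hit = self.entries.get(token)
        if hit:
            return frozenset(hit), True
        ci = self._ci_index.get(token.casefold())
        if ci:
            return frozenset(ci), False
        return frozenset(), False

    def __len__(self) -> int:
        return len(self.entries)


def load_map_table(path: str | Path, species: str = "") -> IdMapTable:
    """Load a TSV mapping table (columns: alias, canonical_id, alias_type).

    A header row naming the columns is accepted and skipped.  Blank alias
    or canonical_id cells raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    table = IdMapTable(species=species)
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["alias", "canonical_id"]:
                continue
            if len(row) < 2:
                raise ParseError("expected columns alias, canonical_id[, alias_type]",
                                 str(path), lineno)
            alias, canonical = row[0].strip(), row[1].strip()
            if not alias or not canonical:
                raise ParseError("blank alias or canonical_id", str(path), lineno)
            table.add(alias, canonical)
    return table


@dataclass
class MappedList:
    """Total partition of an input gene list after identifier mapping.

    Every input token lands in exactly one of: mapped (via its canonical
    id), unmapped, ambiguous, or duplicates_removed, so that
    ``n_input == n_mapped_tokens + |unmapped| + |ambiguous| + duplicates_removed``.
    With ``include_ambiguous`` the candidates of ambiguous tokens are
    appended to ``mapped`` as well (and remain flagged in ``ambiguous``).
    """

    label: str
    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]
    ambiguous: dict[str, tuple[str, ...]]
    duplicates_removed: int
    n_input: int
    n_mapped_tokens: int
    #: input token → canonical id, for the tokens counted as mapped
    resolved: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.mapped)

    def partition_holds(self) -> bool:
        return self.n_input == (
            self.n_mapped_tokens + len(self.unmapped)
            + len(self.ambiguous) + self.duplicates_removed
        )


def map_gene_list(
    tokens: Sequence[str],
    table: IdMapTable,
    include_ambiguous: bool = False,
    label: str = "",
) -> MappedList:
    """Map an input list of identifier strings to canonical ids.

    Repeated input tokens, and distinct tokens resolving to an already
    collected canonical id, are collapsed and counted as duplicates.
    Mapping is idempotent: mapping the mapped output again returns it
    unchanged (canonical ids self-alias uniquely).
    """
    mapped: list[str] = []
    unmapped: list[str] = []
    ambiguous: dict[str, tuple[str, ...]] = {}
    resolved: dict[str, str] = {}
    duplicates = 0
    n_mapped_tokens = 0
    seen_tokens: set[str] = set()
    seen_canonicals: set[str] = set()

    for token in tokens:
        if token in seen_tokens:
            duplicates += 1
            continue
        seen_tokens.add(token)
        candidates, exact = table.lookup(token)
        if not candidates:
            unmapped.append(token)
            continue
        if len(candidates) > 1:
            ambiguous[token] = tuple(sorted(candidates))
            if include_ambiguous:
                for c in sorted(candidates):
                    if c not in seen_canonicals:
                        seen_canonicals.add(c)
                        mapped.append(c)
            continue
        (canonical,) = candidates
        if canonical in seen_canonicals:
            duplicates += 1  # distinct alias of an id already in the list
            continue
        seen_canonicals.add(canonical)
        mapped.append(canonical)
        resolved[token] = canonical
        n_mapped_tokens += 1

    return MappedList(
        label=label,
        mapped=tuple(mapped),
        unmapped=tuple(unmapped),
        ambiguous=ambiguous,
        duplicates_removed=duplicates,
        n_input=len(tokens),
        n_mapped_tokens=n_mapped_tokens,
        resolved=resolved,
    )


def write_mapping_report(mapped_list: MappedList, path: str | Path) -> None:
    """Write the mapped-list partition as TSV (input, status, canonical ids)."""
    lines = ["input\tstatus\tcanonical_id(s)"]
    reverse = {c: t for t, c in mapped_list.resolved.items()}
    for cid in mapped_list.mapped:
        lines.append(f"{reverse.get(cid, cid)}\tmapped\t{cid}")
    for token in mapped_list.unmapped:
        lines.append(f"{token}\tunmapped\t")
    for token, cands in sorted(mapped_list.ambiguous.items()):
        lines.append(f"{token}\tambiguous\t{'|'.join(cands)}")
    lines.append(f"#duplicates_removed\t{mapped_list.duplicates_removed}\t")
    Path(path).write_text("\n".join(lines) + "\n")
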