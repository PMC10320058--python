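"""Gene sets, gene-set collections, and their interchange formats.

A :class:`GeneSet` is a named group of genes sharing an attribute (a GO
term, a pathway, a complex, a phenotype, a tissue); a
:class:`GeneSetCollection` is the unit enrichment runs against, and its
universe (the union of all member sets) is the default test background.

GMT (one set per line: id, description, members...) is the interchange
format for all non-GAF sources; a JSON sidecar carries collection-level
metadata (species, category, provenance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ParseError, SetNotFoundError


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of canonical gene ids."""

    set_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


class GeneSetCollection:
    """Named category of gene sets; the unit against which enrichment runs."""

    def __init__(
        self,
        collection_id: str,
        species: str = "",
        gene_sets: Iterable[GeneSet] = (),
        provenance: Mapping[str, object] | None = None,
    ):
        self.collection_id = collection_id
        self.species = species
        self.gene_sets: dict[str, GeneSet] = {}
        self.provenance: dict[str, object] = dict(provenance or {})
        for gs in gene_sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.gene_sets:
            raise ParseError(f"duplicate gene set id {gene_set.set_id!r}")
        self.gene_sets[gene_set.set_id] = gene_set

    @property
    def universe(self) -> frozenset[str]:
        """Exact union of all member sets (recomputed on access)."""
        out: set[str] = set()
        for gs in self.gene_sets.values():
            out |= gs.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.gene_sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.gene_sets

    def __getitem__(self, set_id: str) -> GeneSet:
        try:
            return self.gene_sets[set_id]
        except KeyError:
            raise SetNotFoundError(set_id) from None


# -- GMT ---------------------------------------------------------------


def read_gmt(
    path: str | Path,
    collection_id: str | None = None,
    species: str = "",
    category: str | None = None,
) -> GeneSetCollection:
    """Read a GMT file (set_id, description, members... per line).

    Duplicate members within a line are deduplicated; duplicate set ids
    across lines are an error.  If a JSON sidecar ``<path>.json`` exists,
    its species/category/provenance metadata is applied.
    """
    path = Path(path)
    sidecar = _read_sidecar(path)
    collection = GeneSetCollection(
        collection_id=collection_id or sidecar.get("collection_id", path.stem),
        species=species or sidecar.get("species", ""),
        provenance=sidecar.get("provenance", {}),
    )
    default_category = category or sidecar.get("category", path.stem)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line needs >=3 tab-separated fields, found {len(fields)}",
                str(path),
                lineno,
            )
        set_id, description = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ParseError(f"gene set {set_id!r} has no members", str(path), lineno)
        try:
            collection.add(
                GeneSet(set_id=set_id, name=description or set_id,
                        category=default_category, members=members)
            )
        except ParseError as exc:
            raise ParseError(str(exc.args[0]), str(path), lineno) from None
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT plus a JSON metadata sidecar ``<path>.json``."""
    path = Path(path)
    lines = []
    for set_id in sorted(collection.gene_sets):
        gs = collection.gene_sets[set_id]
        lines.append("\t".join([gs.set_id, gs.name, *sorted(gs.members)]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    categories = sorted({gs.category for gs in collection})
    sidecar = {
        "collection_id": collection.collection_id,
        "species": collection.species,
        "category": categories[0] if len(categories) == 1 else categories,
        "n_gene_sets": len(collection),
        "universe_size": len(collection.universe),
        "provenance": collection.provenance,
    }
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def _read_sidecar(path: Path) -> dict:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        return {}
    data = json.loads(sidecar_path.read_text())
    if isinstance(data.get("category"), list):
        data = {**data, "category": None}  # mixed categories: fall back to default
    return {k: v for k, v in data.items() if v is not None}


# -- plain-text gene lists --------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list: one identifier per line, '#' comments, order kept."""
    out: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
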