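"""Ontology handling: OBO parsing, ancestor closure ("flattening"), slim mapping.

Gene Ontology and similar controlled vocabularies are directed acyclic
graphs of terms.  Annotation to a term implies annotation to every ancestor
reachable through ``is_a`` and ``part_of`` links, so gene-set construction
needs the transitive closure of the parent relation.  This module parses
OBO 1.2/1.4 flat files into an :class:`Ontology`, computes ancestor sets,
and intersects them with slim subsets (reduced vocabularies of broad terms).

Propagation traverses ``is_a`` and ``part_of`` only; regulates-type links
are ignored, and ``part_of`` links that cross namespaces (aspects) are not
followed, because enrichment categories are per-aspect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import OntologyCycleError, ParseError, TermNotFoundError

PROPAGATED_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class Term:
    """One ontology term (a node of the DAG)."""

    term_id: str
    name: str = ""
    namespace: str = ""
    #: ``(parent_id, relation)`` pairs with relation in {is_a, part_of}
    parents: tuple[tuple[str, str], ...] = ()
    alt_ids: tuple[str, ...] = ()
    is_obsolete: bool = False
    #: ``subset:`` tags from the OBO stanza (slim membership markers)
    subsets: tuple[str, ...] = ()


class Ontology:
    """A DAG of terms keyed by accession, with alt_id resolution.

    Parameters
    ----------
    terms
        Terms keyed by primary accession.  Parent references must resolve
        to existing terms, alt_ids must not collide with primary ids, and
        the parent links must be acyclic; violations raise at construction.
    """

    def __init__(self, terms: Mapping[str, Term]):
        self.terms: dict[str, Term] = dict(terms)
        self._alt: dict[str, str] = {}
        for t in self.terms.values():
            for alt in t.alt_ids:
                if alt in self.terms:
                    raise ParseError(
                        f"alt_id {alt!r} of {t.term_id!r} collides with a primary term id"
                    )
                self._alt[alt] = t.term_id
        for t in self.terms.values():
            for pid, rel in t.parents:
                if pid not in self.terms:
                    raise ParseError(
                        f"term {t.term_id!r} references missing parent {pid!r} ({rel})"
                    )
        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for pid, _rel in self._propagation_parents(t):
                g.add_edge(t.term_id, pid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyCycleError([u for u, _v in cycle] + [cycle[0][0]])

    def _propagation_parents(self, term: Term) -> Iterable[tuple[str, str]]:
        # obsolete terms never propagate; cross-namespace part_of not followed
        if term.is_obsolete:
            return
        for pid, rel in term.parents:
            if rel not in PROPAGATED_RELATIONS:
                continue
            parent = self.terms.get(pid)
            if parent is None:
                continue
            if rel == "part_of" and parent.namespace != term.namespace:
                continue
            yield pid, rel

    # -- lookup ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Return the primary accession for ``term_id`` (alt_ids resolve silently)."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise TermNotFoundError(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[self.resolve(term_id)]

    @property
    def root_ids(self) -> frozenset[str]:
        """Non-obsolete terms with no propagated parent."""
        return frozenset(
            t.term_id
            for t in self.terms.values()
            if not t.is_obsolete and not any(True for _ in self._propagation_parents(t))
        )

    # -- closure --------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via is_a/part_of, excluding itself."""
        tid = self.resolve(term_id)
        cached = self._anc_cache.get(tid)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [pid for pid, _ in self._propagation_parents(self.terms[tid])]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            cached = self._anc_cache.get(cur)
            if cached is not None:
                out |= cached
                continue
            stack.extend(pid for pid, _ in self._propagation_parents(self.terms[cur]))
        result = frozenset(out)
        self._anc_cache[tid] = result
        return result


@dataclass(frozen=True)
class SlimSubset:
    """A named reduced vocabulary: membership of broad "slim" terms."""

    slim_id: str
    member_term_ids: frozenset[str]


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Module-level convenience wrapper for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id)


def map_to_slim(ontology: Ontology, term_id: str, slim: SlimSubset) -> frozenset[str]:
    """Slim terms covering ``term_id``: ({term} ∪ ancestors(term)) ∩ slim members.

    Propagate-then-intersect semantics: a fine-grained annotation maps to
    every slim term above it, which may be none (empty set is a valid
    answer for terms outside the slim's coverage).
    """
    tid = ontology.resolve(term_id)
    return frozenset(({tid} | ontology.ancestors(tid)) & slim.member_term_ids)


def slim_subset(
    ontology: Ontology, slim_id: str, member_ids: Iterable[str]
) -> SlimSubset:
    """Build a validated SlimSubset; members resolve through alt_ids."""
    resolved = frozenset(ontology.resolve(m) for m in member_ids)
    return SlimSubset(slim_id=slim_id, member_term_ids=resolved)


def load_slim(path: str | Path, ontology: Ontology, slim_id: str | None = None) -> SlimSubset:
    """Read a slim from a one-column text file of term ids ('#' comments)."""
    path = Path(path)
    members: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if any(c.isspace() for c in line):
            raise ParseError("expected a single term id per line", str(path), lineno)
        members.append(line)
    return slim_subset(ontology, slim_id or path.stem, members)


def slim_from_subset_tags(ontology: Ontology, slim_id: str) -> SlimSubset:
    """Collect the slim whose members carry ``subset: <slim_id>`` OBO tags."""
    members = [t.term_id for t in ontology.terms.values() if slim_id in t.subsets]
    return SlimSubset(slim_id=slim_id, member_term_ids=frozenset(members))


_KEY_VALUE = re.compile(r"^[\w\-]+\s*:")


def _prevalidate_obo(path: Path) -> None:
    # obonet reports malformed input poorly; give line-numbered errors here
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            continue
        if not _KEY_VALUE.match(line):
            raise ParseError(f"malformed OBO line: {raw!r}", str(path), lineno)


def load_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 file into an :class:`Ontology`.

    is_a and ``relationship: part_of`` links are retained; other
    relationship types are dropped.  Obsolete terms are kept (flagged) but
    excluded from propagation.  Raises :class:`ParseError` on malformed
    stanzas or dangling parents, :class:`OntologyCycleError` on cycles.
    """
    path = Path(path)
    _prevalidate_obo(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet raises rarely after prevalidation
        raise ParseError(f"OBO parse failure: {exc}", str(path)) from exc

    terms: dict[str, Term] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents: list[tuple[str, str]] = []
        if not obsolete:
            for pid in data.get("is_a", []):
                parents.append((pid, "is_a"))
            for entry in data.get("relationship", []):
                rel, _, target = entry.partition(" ")
                if rel == "part_of" and target:
                    parents.append((target.strip(), "part_of"))
        terms[node] = Term(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parents=tuple(parents),
            alt_ids=tuple(data.get("alt_id", [])),
            is_obsolete=obsolete,
            subsets=tuple(data.get("subset", [])),
        )
    try:
        return Ontology(terms)
    except ParseError as exc:
        raise ParseError(f"{exc.args[0]}", str(path)) from None
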