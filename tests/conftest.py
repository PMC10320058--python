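"""Shared fixtures: tiny ontologies, a synthetic fixture directory, helpers."""

from __future__ import annotations

import json
import random
from pathlib import Path

import pytest

from oraset.fixtures import FixtureSpec, generate_fixture
from oraset.ontology import Ontology, Term


def chain_ontology() -> Ontology:
    """C is_a B is_a A."""
    return Ontology({
        "A": Term("A", name="a"),
        "B": Term("B", name="b", parents=(("A", "is_a"),)),
        "C": Term("C", name="c", parents=(("B", "is_a"),)),
    })


def diamond_ontology() -> Ontology:
    """D is_a B, D is_a C, B is_a A, C is_a A."""
    return Ontology({
        "A": Term("A"),
        "B": Term("B", parents=(("A", "is_a"),)),
        "C": Term("C", parents=(("A", "is_a"),)),
        "D": Term("D", parents=(("B", "is_a"), ("C", "is_a"))),
    })


def random_dag_ontology(rng: random.Random, n_terms: int) -> Ontology:
    """Random DAG: each term's parents drawn from earlier terms (acyclic)."""
    terms: dict[str, Term] = {"T000": Term("T000")}
    ids = ["T000"]
    for i in range(1, n_terms):
        tid = f"T{i:03d}"
        n_par = rng.randint(0, min(3, len(ids)))
        parents = tuple(
            (p, rng.choice(["is_a", "part_of"]))
            for p in rng.sample(ids, n_par)
        )
        terms[tid] = Term(tid, parents=parents)
        ids.append(tid)
    return Ontology(terms)


def brute_force_ancestors(ontology: Ontology, term_id: str) -> set[str]:
    """Reachability by exhaustive path enumeration (independent oracle)."""
    out: set[str] = set()

    def walk(tid: str) -> None:
        for pid, rel in ontology.terms[tid].parents:
            if rel in ("is_a", "part_of") and pid not in out:
                out.add(pid)
                walk(pid)

    walk(ontology.resolve(term_id))
    return out


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """One deterministic synthetic fixture shared across the suite."""
    d = tmp_path_factory.mktemp("fixture")
    generate_fixture(FixtureSpec(seed=2024), d)
    return d


@pytest.fixture(scope="session")
def ground_truth(fixture_dir: Path) -> dict:
    return json.loads((fixture_dir / "ground_truth.json").read_text())
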