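"""Tissue-preferential expression classification from an RPKM matrix.

RNA-seq samples (e.g. the dissected-tissue transcriptome compendia
distributed by model-organism databases) are grouped by tissue, gene
expression is averaged per group, and a gene is called preferentially
expressed in a tissue group when its mean RPKM there is at least
``fold_threshold`` (default 3) times the mean in *every* other group and
at least ``min_rpkm`` (default 10).  The floor applies to the candidate
group's mean — genes whose best group averages below 10 RPKM are
excluded.  With a fold threshold above 1 the rule can hold in at most one
group, so the resulting tissue gene sets are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError
from .genesets import GeneSet, GeneSetCollection

DEFAULT_FOLD_THRESHOLD = 3.0
DEFAULT_MIN_RPKM = 10.0


@dataclass
class ExpressionMatrix:
    """Gene × sample RPKM values plus the sample → tissue-group map."""

    values: pd.DataFrame  # rows: genes, columns: samples, non-negative RPKM
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ConfigurationError(f"samples without a tissue group: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ConfigurationError("RPKM values must be non-negative")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({self.sample_groups[s] for s in self.values.columns}))


def load_expression_tsv(
    matrix_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Load the TSV pair: gene × sample RPKM matrix and sample → group map."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r}", str(matrix_path))
    groups: dict[str, str] = {}
    for lineno, raw in enumerate(Path(groups_path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError("expected two columns: sample, tissue_group",
                             str(groups_path), lineno)
        if lineno == 1 and parts[0].lower() == "sample":
            continue
        groups[parts[0]] = parts[1]
    return ExpressionMatrix(values=values.astype(float), sample_groups=groups)


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean RPKM of each gene in each tissue group (gene × group)."""
    mapping = pd.Series({s: matrix.sample_groups[s] for s in matrix.values.columns})
    counts = mapping.value_counts()
    empty = [g for g in set(matrix.sample_groups.values()) if g not in counts.index]
    if empty:
        raise ConfigurationError(f"tissue groups with zero samples: {sorted(empty)}")
    means = matrix.values.T.groupby(mapping).mean().T
    return means.sort_index(axis=1)


@dataclass
class TissueAssignment:
    """At most one preferred tissue group per gene."""

    assignments: dict[str, str]
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    min_rpkm: float = DEFAULT_MIN_RPKM


def classify_preferential(
    means: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_rpkm: float = DEFAULT_MIN_RPKM,
) -> TissueAssignment:
    """Assign each gene to its preferred tissue group, if any.

    Gene g is assigned to group G iff mean(g, G) >= min_rpkm and
    mean(g, G) >= fold_threshold * mean(g, G') for every other group G'.
    Both comparisons are inclusive (>=); a zero mean in another group
    satisfies the fold condition automatically.  Genes meeting the rule
    nowhere stay unassigned.
    """
    if fold_threshold <= 0 or min_rpkm <= 0:
        raise ConfigurationError("fold_threshold and min_rpkm must be positive")
    if means.shape[1] < 2:
        raise ConfigurationError("classification needs at least 2 tissue groups")

    m = means.to_numpy(dtype=float)
    groups = list(means.columns)
    assignments: dict[str, str] = {}
    for i, gene in enumerate(means.index):
        row = m[i]
        # with fold_threshold > 1 at most one group can qualify; scan in
        # column order so any fold_threshold <= 1 tie resolves deterministically
        for j, g in enumerate(groups):
            v = row[j]
            if v < min_rpkm:
                continue
            others = np.delete(row, j)
            if np.all(v >= fold_threshold * others):
                assignments[str(gene)] = g
                break
    return TissueAssignment(
        assignments=assignments, fold_threshold=fold_threshold, min_rpkm=min_rpkm
    )


def tissue_collection(
    assignment: TissueAssignment,
    species: str = "",
    collection_id: str = "tissue-preferential-expression",
) -> GeneSetCollection:
    """One gene set per tissue group with at least one assigned gene."""
    members: dict[str, set[str]] = {}
    for gene, group in assignment.assignments.items():
        members.setdefault(group, set()).add(gene)
    collection = GeneSetCollection(
        collection_id=collection_id,
        species=species,
        provenance={
            "source": "RPKM expression matrix",
            "fold_threshold": assignment.fold_threshold,
            "min_rpkm": assignment.min_rpkm,
            "n_assigned_genes": len(assignment.assignments),
        },
    )
    for group in sorted(members):
        collection.add(
            GeneSet(set_id=group, name=group,
                    category="tissue-preferential-expression",
                    members=frozenset(members[group]))
        )
    return collection
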