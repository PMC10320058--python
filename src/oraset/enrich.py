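"""Hypergeometric over-representation testing with multiple-testing control.

The statistic: draw n genes (the input list, restricted to the background)
from a background of N genes containing K members of a gene set; the
over-representation p-value is the upper tail

    P(X >= k) = sum_{j=k..min(n,K)} C(K,j) C(N-K, n-j) / C(N,n)

for the observed overlap k.  The test is one-sided (over-representation
only).  Three family-wise adjustments are computed over the family of all
sets tested in one call: Bonferroni, Benjamini–Hochberg (BH) step-up FDR,
and Benjamini–Yekutieli (BY, BH multiplied by c(m) = sum_{i=1..m} 1/i for
arbitrary dependence).  Fold enrichment is (k/n)/(K/N).

The default background is the collection universe — every gene annotated
in the selected category; a user-supplied background (e.g. the genes in a
focused sub-library screen) is intersected with that universe first and
the discarded count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError, EmptyInputError
from .genesets import GeneSetCollection
from .idmap import MappedList

ADJUST_METHODS = ("bonferroni", "bh", "by")
CUTOFF_COLUMNS = ("raw",) + ADJUST_METHODS


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), numerically stable.

    Raises :class:`DomainError` naming the offending count when the
    preconditions 0 <= K <= N, 0 <= n <= N, 0 <= k <= min(n, K) fail.
    """
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise DomainError(f"{name}={value!r} must be a non-negative integer")
    if K > N:
        raise DomainError(f"K={K} exceeds N={N}")
    if n > N:
        raise DomainError(f"n={n} exceeds N={N}")
    if k > min(n, K):
        raise DomainError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy computes it in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def adjust_pvalues(p: Sequence[float], method: str) -> list[float]:
    """Adjust p-values for multiple testing; output order matches input.

    ``bonferroni``: min(1, p*m).  ``bh``: Benjamini–Hochberg step-up with
    monotonicity enforcement.  ``by``: Benjamini–Yekutieli — the BH values
    scaled by c(m) = sum_{i=1..m} 1/i before capping at 1.
    """
    if method not in ADJUST_METHODS:
        raise ConfigurationError(
            f"unknown adjustment method {method!r}; expected one of {ADJUST_METHODS}"
        )
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise DomainError("p must be a non-empty 1-d sequence")
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        bad = arr[(arr < 0) | (arr > 1) | np.isnan(arr)][0]
        raise DomainError(f"p-value {bad!r} outside [0, 1]")
    m = arr.size
    if method == "bonferroni":
        return list(np.minimum(arr * m, 1.0))
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    monotone = np.minimum.accumulate(ranked[::-1])[::-1]
    if method == "by":
        monotone = monotone * np.sum(1.0 / np.arange(1, m + 1))
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(monotone, 1.0)
    return list(adjusted)


@dataclass(frozen=True)
class Background:
    """The gene population against which over-representation is judged."""

    source: str  # collection_universe | user_supplied
    genes: frozenset[str]
    #: user-supplied genes outside the collection universe (discarded)
    discarded: int = 0


def resolve_background(
    collection: GeneSetCollection, genes: Iterable[str] | None = None
) -> Background:
    """Default to the collection universe; intersect user genes with it."""
    universe = collection.universe
    if genes is None:
        return Background(source="collection_universe", genes=universe)
    supplied = frozenset(genes)
    kept = supplied & universe
    return Background(
        source="user_supplied", genes=kept, discarded=len(supplied) - len(kept)
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per gene set: the 2x2 counts, p-values and overlap membership."""

    set_id: str
    name: str
    category: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: dict[str, float]
    fold_enrichment: float | None
    overlap_members: tuple[str, ...]


@dataclass(frozen=True)
class UncoveredReport:
    """Input genes belonging to no set in the selected collection."""

    genes: tuple[str, ...]
    fraction: float


def _input_genes(gene_list: MappedList | Iterable[str]) -> frozenset[str]:
    if isinstance(gene_list, MappedList):
        return gene_list.genes
    return frozenset(gene_list)


def run_enrichment(
    gene_list: MappedList | Iterable[str],
    collection: GeneSetCollection,
    background: Background | Iterable[str] | None = None,
    min_set_size: int = 1,
    p_cutoff: float | None = None,
    cutoff_on: str = "bh",
) -> tuple[list[EnrichmentResult], UncoveredReport]:
    """Test one gene list against every set in a collection.

    Every set whose background-restricted size is at least ``min_set_size``
    is tested; the three adjustments are computed over exactly that family.
    Results come back sorted by raw p (set_id breaks ties) and filtered by
    ``p_cutoff`` on the chosen column (``raw``/``bonferroni``/``bh``/``by``)
    when given.  Zero-overlap sets are reported (p = 1) unless the cutoff
    removes them, so multi-list comparison matrices stay dense.

    The uncovered report — input genes in no set of the collection — is
    computed against the full collection, ignoring ``min_set_size``.
    """
    if cutoff_on not in CUTOFF_COLUMNS:
        raise ConfigurationError(
            f"cutoff_on must be one of {CUTOFF_COLUMNS}, got {cutoff_on!r}"
        )
    if min_set_size < 0:
        raise ConfigurationError("min_set_size must be >= 0")
    if not isinstance(background, Background):
        background = resolve_background(collection, background)
    bg = background.genes
    genes = _input_genes(gene_list) & bg
    n = len(genes)
    if n == 0:
        raise EmptyInputError(
            "no input genes remain after background intersection",
            diagnostics={
                "input_size": len(_input_genes(gene_list)),
                "background_size": len(bg),
                "background_source": background.source,
                "background_discarded": background.discarded,
            },
        )
    N = len(bg)

    tested: list[EnrichmentResult] = []
    pvals: list[float] = []
    for set_id in sorted(collection.gene_sets):
        gs = collection.gene_sets[set_id]
        members_bg = gs.members & bg
        K = len(members_bg)
        if K < min_set_size:
            continue
        overlap = genes & members_bg
        k = len(overlap)
        p = hypergeom_pvalue(N, K, n, k)
        fold = None if (n == 0 or K == 0) else (k / n) / (K / N)
        tested.append(
            EnrichmentResult(
                set_id=gs.set_id, name=gs.name, category=gs.category,
                N=N, K=K, n=n, k=k, p_raw=p, p_adj={},
                fold_enrichment=fold, overlap_members=tuple(sorted(overlap)),
            )
        )
        pvals.append(p)

    if tested:
        adjusted = {m: adjust_pvalues(pvals, m) for m in ADJUST_METHODS}
        tested = [
            EnrichmentResult(
                **{**r.__dict__, "p_adj": {m: adjusted[m][i] for m in ADJUST_METHODS}}
            )
            for i, r in enumerate(tested)
        ]
    tested.sort(key=lambda r: (r.p_raw, r.set_id))

    if p_cutoff is not None:
        tested = [r for r in tested if _cutoff_value(r, cutoff_on) <= p_cutoff]

    covered: set[str] = set()
    for gs in collection:
        covered |= gs.members & genes
    uncovered_genes = tuple(sorted(genes - covered))
    uncovered = UncoveredReport(genes=uncovered_genes, fraction=len(uncovered_genes) / n)
    return tested, uncovered


def _cutoff_value(result: EnrichmentResult, column: str) -> float:
    return result.p_raw if column == "raw" else result.p_adj[column]


# -- TSV serialization -------------------------------------------------

RESULT_COLUMNS = (
    "set_id", "name", "category", "N", "K", "n", "k",
    "p_raw", "p_bonferroni", "p_bh", "p_by", "fold_enrichment", "overlap_members",
)


def results_to_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as a TSV table (deterministic formatting)."""
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        fold = "" if r.fold_enrichment is None else format(r.fold_enrichment, ".6g")
        lines.append("\t".join([
            r.set_id, r.name, r.category, str(r.N), str(r.K), str(r.n), str(r.k),
            format(r.p_raw, ".6e"),
            format(r.p_adj["bonferroni"], ".6e"),
            format(r.p_adj["bh"], ".6e"),
            format(r.p_adj["by"], ".6e"),
            fold,
            "|".join(r.overlap_members),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_tsv(path: str | Path) -> list[EnrichmentResult]:
    """Read back a results TSV written by :func:`results_to_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(RESULT_COLUMNS):
        raise DomainError(f"not an enrichment results table: {path}")
    out: list[EnrichmentResult] = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(EnrichmentResult(
            set_id=f[0], name=f[1], category=f[2],
            N=int(f[3]), K=int(f[4]), n=int(f[5]), k=int(f[6]),
            p_raw=float(f[7]),
            p_adj={"bonferroni": float(f[8]), "bh": float(f[9]), "by": float(f[10])},
            fold_enrichment=float(f[11]) if f[11] else None,
            overlap_members=tuple(m for m in f[12].split("|") if m) if len(f) > 12 else (),
        ))
    return out


def uncovered_to_tsv(report: UncoveredReport, path: str | Path) -> None:
    """Write the uncovered-genes report as TSV."""
    lines = ["gene_id", *report.genes, f"#fraction_uncovered\t{report.fraction:.6g}"]
    Path(path).write_text("\n".join(lines) + "\n")
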