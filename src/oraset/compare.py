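"""Multi-list enrichment comparison and plot-data export.

Screens and omics studies usually yield several related gene lists (hits
of five pathway screens, interactors of four bait proteins, ...).  Each
list is analysed independently — the multiple-testing family is per list,
so one list's adjusted values never depend on another's — and the results
are assembled into a sets × lists :class:`ComparisonMatrix` holding, for
every gene set that passes the cutoff in at least one list, the adjusted
p, fold enrichment and overlap count in every list.  Cells for sets that
were not tested in a list carry a p = 1 marker rather than a blank, so
heatmap/dot-plot exports are dense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrich import (
    Background,
    EnrichmentResult,
    UncoveredReport,
    _cutoff_value,
    run_enrichment,
)
from .errors import ConfigurationError, DomainError
from .genesets import GeneSetCollection
from .idmap import MappedList

#: p-values below this are clamped before -log10 so plot coordinates stay finite
P_FLOOR = 1e-300

#: (p_adj, fold_enrichment, k) marker for a set/list pair never tested
MISSING_CELL = (1.0, None, 0)


@dataclass
class ComparisonMatrix:
    """lists × gene-sets grid of (p_adj, fold_enrichment, k) triples."""

    set_ids: tuple[str, ...]          # rows: sets passing the cutoff in >=1 list
    list_labels: tuple[str, ...]      # columns
    cells: dict[tuple[str, str], tuple[float, float | None, int]]
    method: str                       # adjustment filling p_adj ('raw' allowed)
    set_names: dict[str, str] = field(default_factory=dict)

    def cell(self, set_id: str, label: str) -> tuple[float, float | None, int]:
        return self.cells.get((set_id, label), MISSING_CELL)


def run_multi(
    lists: Sequence[MappedList] | Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    background: Background | Iterable[str] | None = None,
    min_set_size: int = 1,
    p_cutoff: float | None = 0.05,
    cutoff_on: str = "bh",
) -> tuple[dict[str, list[EnrichmentResult]], dict[str, UncoveredReport], ComparisonMatrix]:
    """Run enrichment per list and assemble the comparison matrix.

    Returns the *full* per-list result tables (no cutoff applied, so every
    matrix cell is bitwise identical to its single-list counterpart), the
    per-list uncovered reports, and the matrix whose rows are the sets
    passing the cutoff in at least one list.
    """
    if isinstance(lists, Mapping):
        items = [(label, genes) for label, genes in lists.items()]
    else:
        items = [(ml.label, ml) for ml in lists]
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate list labels: {labels}")
    if not items:
        raise ConfigurationError("at least one gene list is required")

    results_by_label: dict[str, list[EnrichmentResult]] = {}
    uncovered_by_label: dict[str, UncoveredReport] = {}
    passing: set[str] = set()
    for label, genes in items:
        results, uncovered = run_enrichment(
            genes, collection, background=background,
            min_set_size=min_set_size, p_cutoff=None, cutoff_on=cutoff_on,
        )
        results_by_label[label] = results
        uncovered_by_label[label] = uncovered
        for r in results:
            if p_cutoff is None or _cutoff_value(r, cutoff_on) <= p_cutoff:
                passing.add(r.set_id)

    set_ids = tuple(sorted(passing))
    cells: dict[tuple[str, str], tuple[float, float | None, int]] = {}
    set_names: dict[str, str] = {}
    for label in labels:
        for r in results_by_label[label]:
            if r.set_id in passing:
                cells[(r.set_id, label)] = (_cutoff_value(r, cutoff_on),
                                            r.fold_enrichment, r.k)
                set_names[r.set_id] = r.name
    matrix = ComparisonMatrix(
        set_ids=set_ids, list_labels=tuple(labels), cells=cells,
        method=cutoff_on, set_names=set_names,
    )
    return results_by_label, uncovered_by_label, matrix


def matrix_to_tsv(matrix: ComparisonMatrix, path: str | Path) -> None:
    """Write the comparison matrix as a long-format TSV."""
    lines = ["set_id\tname\tlist_label\tp_adj\tfold_enrichment\tk"]
    for set_id in matrix.set_ids:
        for label in matrix.list_labels:
            p, fold, k = matrix.cell(set_id, label)
            fold_s = "" if fold is None else format(fold, ".6g")
            lines.append("\t".join([
                set_id, matrix.set_names.get(set_id, set_id), label,
                format(p, ".6e"), fold_s, str(k),
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- plot data ---------------------------------------------------------

PLOT_KINDS = ("bar", "heatmap", "dotplot")


def neg_log10(p: float) -> float:
    """-log10 with the :data:`P_FLOOR` clamp (p=1 maps to height 0)."""
    import math

    return -math.log10(max(float(p), P_FLOOR)) + 0.0


def export_plot_data(
    data: ComparisonMatrix | Sequence[EnrichmentResult],
    kind: str,
    method: str = "bh",
) -> dict:
    """Build a deterministic plot-data document.

    ``bar`` (single result table): per-set -log10(p_adj) bar heights with a
    fold-enrichment colour channel.  ``heatmap`` (matrix): sets × lists
    grid of -log10(p_adj).  ``dotplot`` (matrix): same grid with dot size
    k and colour -log10(p_adj).  Missing matrix cells map to 0 (p = 1).
    """
    if kind not in PLOT_KINDS:
        raise ConfigurationError(f"unknown plot kind {kind!r}; expected {PLOT_KINDS}")
    if kind == "bar":
        if isinstance(data, ComparisonMatrix):
            raise ConfigurationError("bar plots take a single-list result table")
        results = list(data)
        if not results:
            raise DomainError("no results to plot")
        return {
            "kind": "bar",
            "method": method,
            "bars": [
                {
                    "set_id": r.set_id,
                    "name": r.name,
                    "height": neg_log10(r.p_adj[method] if method != "raw" else r.p_raw),
                    "fold_enrichment": r.fold_enrichment,
                    "k": r.k,
                }
                for r in results
            ],
        }
    if not isinstance(data, ComparisonMatrix):
        raise ConfigurationError(f"{kind} plots take a ComparisonMatrix")
    if not data.set_ids or not data.list_labels:
        raise DomainError("comparison matrix is empty; nothing to plot")
    doc: dict = {
        "kind": kind,
        "method": data.method,
        "rows": list(data.set_ids),
        "row_names": [data.set_names.get(s, s) for s in data.set_ids],
        "cols": list(data.list_labels),
        "values": [
            [neg_log10(data.cell(s, l)[0]) for l in data.list_labels]
            for s in data.set_ids
        ],
    }
    if kind == "dotplot":
        doc["sizes"] = [
            [data.cell(s, l)[2] for l in data.list_labels] for s in data.set_ids
        ]
    return doc


def write_plot_data(doc: dict, path: str | Path) -> None:
    """Serialize a plot-data document deterministically (sorted keys)."""
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def render_plot(doc: dict, path: str | Path) -> None:
    """Render a static image (PNG/SVG by extension) from a plot-data document."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if doc["kind"] == "bar":
        bars = doc["bars"]
        fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(bars))))
        heights = [b["height"] for b in bars]
        folds = [b["fold_enrichment"] or 0 for b in bars]
        cmap = plt.get_cmap("viridis")
        vmax = max(folds) or 1.0
        ax.barh([b["name"] for b in bars][::-1], heights[::-1],
                color=[cmap(f / vmax) for f in folds][::-1])
        ax.set_xlabel(f"-log10 adjusted p ({doc['method']})")
    else:
        values = np.array(doc["values"], dtype=float)
        fig, ax = plt.subplots(
            figsize=(max(3, 0.8 * len(doc["cols"])), max(2, 0.35 * len(doc["rows"])))
        )
        if doc["kind"] == "heatmap":
            im = ax.imshow(values, aspect="auto", cmap="viridis")
            fig.colorbar(im, ax=ax, label="-log10 adjusted p")
        else:  # dotplot
            sizes = np.array(doc["sizes"], dtype=float)
            ys, xs = np.indices(values.shape)
            sc = ax.scatter(xs.ravel(), ys.ravel(), s=10 + 20 * sizes.ravel(),
                            c=values.ravel(), cmap="viridis")
            fig.colorbar(sc, ax=ax, label="-log10 adjusted p")
            ax.invert_yaxis()
        ax.set_xticks(range(len(doc["cols"])), doc["cols"], rotation=45, ha="right")
        ax.set_yticks(range(len(doc["rows"])), doc["row_names"])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
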