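"""Multi-list comparison matrices, bipartite graphs, plot-data export."""

from __future__ import annotations

import itertools
import json
import random

import pytest

from oraset.compare import (
    MISSING_CELL,
    ComparisonMatrix,
    export_plot_data,
    matrix_to_tsv,
    neg_log10,
    run_multi,
    write_plot_data,
)
from oraset.enrich import run_enrichment
from oraset.errors import ConfigurationError, DomainError, SetNotFoundError
from oraset.genesets import GeneSet, GeneSetCollection
from oraset.graphs import build_graph, to_networkx, write_graphml, write_node_edge_tsv


@pytest.fixture
def collection() -> GeneSetCollection:
    genes = [f"g{i}" for i in range(1, 21)]
    return GeneSetCollection("c", gene_sets=[
        GeneSet("S1", "first", "t", frozenset(genes[:5])),
        GeneSet("S2", "second", "t", frozenset(genes[5:10])),
        GeneSet("ALL", "universe", "t", frozenset(genes)),
    ])


class TestRunMulti:
    def test_identical_lists_identical_columns(self, collection):
        lists = {"A": ["g1", "g2", "g3"], "B": ["g1", "g2", "g3"]}
        _results, _unc, matrix = run_multi(lists, collection, p_cutoff=0.5,
                                           cutoff_on="raw")
        for sid in matrix.set_ids:
            assert matrix.cell(sid, "A") == matrix.cell(sid, "B")

    def test_union_of_passing_sets(self, collection):
        lists = {"A": ["g1", "g2", "g3", "g4"], "B": ["g6", "g7", "g8", "g9"]}
        _r, _u, matrix = run_multi(lists, collection, p_cutoff=0.01, cutoff_on="raw")
        assert set(matrix.set_ids) == {"S1", "S2"}
        # each row passes in exactly one column here
        for sid, passing_label in [("S1", "A"), ("S2", "B")]:
            p_pass = matrix.cell(sid, passing_label)[0]
            p_other = matrix.cell(sid, "A" if passing_label == "B" else "B")[0]
            assert p_pass <= 0.01 < p_other

    def test_cells_bitwise_equal_to_single_list_results(self, collection):
        lists = {"A": ["g1", "g2", "g3"], "B": ["g6", "g7"]}
        results, _u, matrix = run_multi(lists, collection, p_cutoff=0.9,
                                        cutoff_on="bh")
        for label, genes in lists.items():
            single, _ = run_enrichment(genes, collection, cutoff_on="bh")
            by_id = {r.set_id: r for r in single}
            for sid in matrix.set_ids:
                p, fold, k = matrix.cell(sid, label)
                r = by_id[sid]
                assert (p, fold, k) == (r.p_adj["bh"], r.fold_enrichment, r.k)

    def test_single_list_degenerates_to_result_table(self, collection):
        results, _u, matrix = run_multi({"A": ["g1", "g2", "g3"]}, collection,
                                        p_cutoff=0.5, cutoff_on="raw")
        passing = [r for r in results["A"] if r.p_raw <= 0.5]
        assert set(matrix.set_ids) == {r.set_id for r in passing}

    def test_duplicate_labels_rejected(self, collection):
        from oraset.idmap import MappedList

        ml = MappedList("same", ("g1",), (), {}, 0, 1, 1)
        with pytest.raises(ConfigurationError, match="duplicate"):
            run_multi([ml, ml], collection)

    def test_missing_cells_carry_p1_marker(self, collection):
        # S2 never tested for a list whose background excludes its genes
        assert MISSING_CELL == (1.0, None, 0)
        lists = {"A": ["g1", "g2", "g3", "g4"]}
        _r, _u, matrix = run_multi(lists, collection, p_cutoff=0.5, cutoff_on="raw")
        assert matrix.cell("NOT_A_SET", "A") == MISSING_CELL

    def test_matrix_tsv_deterministic(self, collection, tmp_path):
        lists = {"A": ["g1", "g2", "g3"], "B": ["g6", "g7"]}
        out1, out2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        for out in (out1, out2):
            _r, _u, matrix = run_multi(lists, collection, p_cutoff=0.9)
            matrix_to_tsv(matrix, out)
        assert out1.read_bytes() == out2.read_bytes()


class TestBuildGraph:
    def brute_force(self, sets: dict[str, set[str]], input_genes: set[str]):
        edges = {(sid, g) for sid, members in sets.items()
                 for g in members if g in input_genes}
        set_nodes = {sid for sid, _ in edges}
        gene_nodes = {g for _, g in edges}
        return set_nodes, gene_nodes, edges

    def test_worked_overlap_example(self):
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S1", "s1", "t", frozenset({"g1", "g2"})),
            GeneSet("S2", "s2", "t", frozenset({"g2", "g3"})),
        ])
        results, _ = run_enrichment(["g1", "g2", "g3"], coll)
        graph = build_graph(results, ["S1", "S2"])
        assert len(graph.set_nodes) == 2
        assert len(graph.gene_nodes) == 3
        assert len(graph.edges) == 4
        degree = {g: sum(1 for _s, gg in graph.edges if gg == g)
                  for g in graph.gene_nodes}
        assert degree["g2"] == 2

    def test_zero_overlap_set_omitted(self):
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S1", "s1", "t", frozenset({"g1"})),
            GeneSet("S2", "s2", "t", frozenset({"g9"})),
        ])
        results, _ = run_enrichment(["g1"], coll)
        graph = build_graph(results, ["S1", "S2"])
        assert graph.set_nodes == ("S1",)  # no orphan nodes

    def test_empty_selection_empty_graph(self):
        graph = build_graph([], [])
        assert graph.nodes == () and graph.edges == ()

    def test_unknown_set_raises(self):
        with pytest.raises(SetNotFoundError):
            build_graph([], ["GHOST"])

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        genes = [f"g{i}" for i in range(15)]
        sets = {
            f"S{j}": set(rng.sample(genes, rng.randint(1, 8)))
            for j in range(rng.randint(1, 5))
        }
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet(sid, sid, "t", frozenset(m)) for sid, m in sets.items()
        ])
        input_genes = set(rng.sample(genes, rng.randint(1, 10)))
        try:
            results, _ = run_enrichment(input_genes, coll)
        except Exception:
            return  # input disjoint from universe: nothing to test
        graph = build_graph(results, list(sets))
        bf_sets, bf_genes, bf_edges = self.brute_force(
            sets, input_genes & coll.universe)
        assert set(graph.set_nodes) == bf_sets
        assert set(graph.gene_nodes) == bf_genes
        assert set(graph.edges) == bf_edges

    def test_edges_connect_sets_to_member_input_genes(self):
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S1", "s1", "t", frozenset({"g1", "g2", "g3"})),
        ])
        results, _ = run_enrichment(["g1", "g3"], coll)
        graph = build_graph(results, ["S1"])
        for sid, gid in graph.edges:
            assert gid in coll[sid].members
            assert gid in {"g1", "g3"}

    def test_graphml_and_tsv_export(self, tmp_path):
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S1", "s1", "t", frozenset({"g1", "g2"})),
        ])
        results, _ = run_enrichment(["g1", "g2"], coll)
        graph = build_graph(results, ["S1"])
        write_graphml(graph, tmp_path / "g.graphml")
        write_node_edge_tsv(graph, tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert "graphml" in (tmp_path / "g.graphml").read_text()
        assert (tmp_path / "n.tsv").read_text().startswith("id\tkind\tlabel")
        nxg = to_networkx(graph)
        assert nxg.number_of_nodes() == 3 and nxg.number_of_edges() == 2


class TestPlotData:
    def test_bar_heights_are_neg_log10(self, collection):
        results, _ = run_enrichment(["g1", "g2", "g3", "g4"], collection)
        doc = export_plot_data(results, "bar", method="raw")
        by_id = {b["set_id"]: b for b in doc["bars"]}
        assert by_id["ALL"]["height"] == 0.0  # p = 1
        for r in results:
            assert by_id[r.set_id]["height"] == pytest.approx(neg_log10(r.p_raw))

    def test_p_001_gives_height_2(self):
        assert neg_log10(0.01) == pytest.approx(2.0)
        assert neg_log10(1.0) == 0.0
        assert neg_log10(0.0) == pytest.approx(300.0)  # clamped floor

    def test_heatmap_missing_cell_maps_to_zero(self, collection):
        lists = {"A": ["g1", "g2", "g3", "g4"], "B": ["g6", "g7", "g8", "g9"]}
        _r, _u, matrix = run_multi(lists, collection, p_cutoff=0.05, cutoff_on="raw")
        # force a missing pair by adding a row id absent from one list's results
        doc = export_plot_data(matrix, "heatmap")
        assert doc["rows"] == list(matrix.set_ids)
        i = doc["rows"].index("S1")
        j = doc["cols"].index("B")
        p_b = matrix.cell("S1", "B")[0]
        assert doc["values"][i][j] == pytest.approx(neg_log10(p_b))

    def test_dotplot_sizes_are_overlap_counts(self, collection):
        lists = {"A": ["g1", "g2", "g3"]}
        _r, _u, matrix = run_multi(lists, collection, p_cutoff=0.9, cutoff_on="raw")
        doc = export_plot_data(matrix, "dotplot")
        i = doc["rows"].index("S1")
        assert doc["sizes"][i][0] == matrix.cell("S1", "A")[2]

    def test_empty_matrix_is_informative_error(self):
        empty = ComparisonMatrix((), (), {}, "bh")
        with pytest.raises(DomainError, match="empty"):
            export_plot_data(empty, "heatmap")

    def test_export_byte_deterministic(self, collection, tmp_path):
        results, _ = run_enrichment(["g1", "g2", "g3"], collection)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_plot_data(export_plot_data(results, "bar"), p1)
        write_plot_data(export_plot_data(results, "bar"), p2)
        assert p1.read_bytes() == p2.read_bytes()
        json.loads(p1.read_text())  # valid JSON
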