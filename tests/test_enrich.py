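"""Hypergeometric test, p-value adjustments, and the enrichment runner."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oraset.enrich import (
    Background,
    adjust_pvalues,
    hypergeom_pvalue,
    read_results_tsv,
    resolve_background,
    results_to_tsv,
    run_enrichment,
)
from oraset.errors import ConfigurationError, DomainError, EmptyInputError
from oraset.genesets import GeneSet, GeneSetCollection


def enumeration_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Oracle: enumerate all C(N, n) draws and count those with >= k marked."""
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(marked.intersection(draw)) >= k)
    return hits / math.comb(N, n)


class TestHypergeomPvalue:
    def test_worked_example_against_enumeration(self):
        # 4 of 4 drawn from a 5-marked set in a 10-gene universe
        assert enumeration_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210)
        assert hypergeom_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_k_zero_is_one(self):
        for N, K, n in [(10, 5, 4), (100, 0, 10), (7, 7, 0)]:
            assert hypergeom_pvalue(N, K, n, 0) == 1.0

    def test_fully_marked_universe(self):
        assert hypergeom_pvalue(8, 8, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_random_counts(self, seed):
        rng = random.Random(seed)
        N = rng.randint(1, 11)
        K = rng.randint(0, N)
        n = rng.randint(0, N)
        k = rng.randint(0, min(n, K))
        assert hypergeom_pvalue(N, K, n, k) == pytest.approx(
            enumeration_pvalue(N, K, n, k), abs=1e-12
        )

    def test_monotone_nonincreasing_in_k(self):
        N, K, n = 40, 12, 15
        ps = [hypergeom_pvalue(N, K, n, k) for k in range(min(n, K) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "N,K,n,k,offender",
        [(10, 11, 4, 0, "K"), (10, 5, 11, 0, "n"), (10, 5, 4, 5, "k"), (-1, 0, 0, 0, "N")],
    )
    def test_precondition_violations_name_offender(self, N, K, n, k, offender):
        with pytest.raises(DomainError, match=offender):
            hypergeom_pvalue(N, K, n, k)

    def test_numerically_stable_at_scale(self):
        # extreme overlap in a genome-scale background stays a finite log-space result
        p = hypergeom_pvalue(15000, 200, 300, 150)
        assert 0 < p < 1e-100


class TestAdjustPvalues:
    def test_single_test_identity(self):
        assert adjust_pvalues([0.01], "bonferroni") == [0.01]

    def test_bh_step_up_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_by_is_bh_times_harmonic_sum(self):
        # c(4) = 1 + 1/2 + 1/3 + 1/4 = 25/12
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "by")
        assert out == pytest.approx([0.04 * 25 / 12] * 4)

    def test_output_order_matches_input(self):
        p = [0.04, 0.001, 0.9, 0.02]
        out = adjust_pvalues(p, "bonferroni")
        assert out == pytest.approx([min(1, x * 4) for x in p])

    def test_invalid_p_rejected(self):
        with pytest.raises(DomainError):
            adjust_pvalues([0.5, 1.2], "bh")
        with pytest.raises(ConfigurationError):
            adjust_pvalues([0.5], "holm")

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_reference_and_ordering(self, p):
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        by = adjust_pvalues(p, "by")
        assert np.allclose(bonf, multipletests(p, method="bonferroni")[1], atol=1e-12)
        assert np.allclose(bh, multipletests(p, method="fdr_bh")[1], atol=1e-12)
        assert np.allclose(by, multipletests(p, method="fdr_by")[1], atol=1e-12)
        for raw, a_bh, a_by, a_bonf in zip(p, bh, by, bonf):
            # BY can exceed Bonferroni for small ranks; these hold universally
            assert raw <= a_bh + 1e-15
            assert a_bh <= a_by + 1e-15
            assert a_bh <= a_bonf + 1e-15


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    genes = [f"g{i}" for i in range(1, 11)]
    return GeneSetCollection("toy", gene_sets=[
        GeneSet("S1", "marked", "test", frozenset(genes[:5])),
        GeneSet("ALL", "universe", "test", frozenset(genes)),
    ])


class TestRunEnrichment:
    def test_worked_example_counts_and_fold(self, toy_collection):
        results, uncovered = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        r = {x.set_id: x for x in results}["S1"]
        assert (r.N, r.K, r.n, r.k) == (10, 5, 4, 4)
        assert r.p_raw == pytest.approx(5 / 210, abs=1e-12)
        assert r.fold_enrichment == pytest.approx(2.0)
        assert r.overlap_members == ("g1", "g2", "g3", "g4")
        assert uncovered.genes == () and uncovered.fraction == 0.0

    def test_input_outside_all_sets(self, toy_collection):
        toy_collection.add(GeneSet("EXTRA", "x", "test", frozenset({"h1", "h2"})))
        results, uncovered = run_enrichment(
            ["h1", "h2"], toy_collection, min_set_size=3)
        assert all(r.k == 0 or r.set_id == "EXTRA" for r in results)
        rs = {r.set_id: r for r in results}
        assert rs["S1"].k == 0 and rs["S1"].p_raw == 1.0
        # EXTRA is below min_set_size, so not tested; but its members cover
        # the input, so nothing is uncovered
        assert "EXTRA" not in rs
        assert uncovered.fraction == 0.0

    def test_uncovered_fraction_one(self):
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S", "s", "t", frozenset({"a", "b"})),
        ])
        bg = Background("user_supplied", frozenset({"a", "b", "x", "y"}))
        results, uncovered = run_enrichment(["x", "y"], coll, background=bg)
        assert all(r.p_raw == 1.0 for r in results)
        assert uncovered.fraction == 1.0

    def test_empty_after_background_raises_with_diagnostics(self, toy_collection):
        with pytest.raises(EmptyInputError) as err:
            run_enrichment(["not_a_gene"], toy_collection)
        assert err.value.diagnostics["input_size"] == 1

    def test_bonferroni_cutoff_equals_raw_for_single_test(self):
        # min_set_size leaves exactly one tested set, so m=1 and the
        # bonferroni cutoff behaves identically to the raw cutoff
        coll = GeneSetCollection("c", gene_sets=[
            GeneSet("S1", "s", "t", frozenset({"g1", "g2", "g3", "g4", "g5"})),
            GeneSet("FILLER", "f", "t", frozenset({"g6", "g7", "g8"})),
        ])
        raw, _ = run_enrichment(["g1", "g2", "g3", "g4"], coll, min_set_size=4,
                                p_cutoff=0.5, cutoff_on="raw")
        bonf, _ = run_enrichment(["g1", "g2", "g3", "g4"], coll, min_set_size=4,
                                 p_cutoff=0.5, cutoff_on="bonferroni")
        assert [r.set_id for r in raw] == [r.set_id for r in bonf] == ["S1"]
        assert raw[0].p_adj["bonferroni"] == raw[0].p_raw

    def test_adjustment_family_is_tested_sets(self, toy_collection):
        results, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        # two tested sets -> bonferroni doubles the raw p (capped at 1)
        for r in results:
            assert r.p_adj["bonferroni"] == pytest.approx(min(1.0, 2 * r.p_raw))

    def test_results_sorted_by_p_then_set_id(self, toy_collection):
        results, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        keys = [(r.p_raw, r.set_id) for r in results]
        assert keys == sorted(keys)

    def test_invariant_to_input_order_and_duplicates(self, toy_collection):
        a, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        b, _ = run_enrichment(["g4", "g2", "g1", "g3", "g1", "g2"], toy_collection)
        assert a == b

    def test_background_shrink_preserves_k(self, toy_collection):
        full, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        shrunk_bg = Background("user_supplied", frozenset(
            {"g1", "g2", "g3", "g4", "g5"}))  # input ∪ S1 only
        shrunk, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection,
                                   background=shrunk_bg)
        by_id_full = {r.set_id: r for r in full}
        for r in shrunk:
            assert r.k == by_id_full[r.set_id].k

    def test_user_background_intersected_and_discard_counted(self, toy_collection):
        bg = resolve_background(toy_collection, ["g1", "g2", "g3", "alien"])
        assert bg.source == "user_supplied"
        assert bg.genes == {"g1", "g2", "g3"}
        assert bg.discarded == 1

    def test_results_tsv_round_trip(self, toy_collection, tmp_path):
        results, _ = run_enrichment(["g1", "g2", "g3", "g4"], toy_collection)
        path = tmp_path / "results.tsv"
        results_to_tsv(results, path)
        back = read_results_tsv(path)
        assert [r.set_id for r in back] == [r.set_id for r in results]
        assert back[0].overlap_members == results[0].overlap_members
        assert back[0].p_raw == pytest.approx(results[0].p_raw, rel=1e-5)
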