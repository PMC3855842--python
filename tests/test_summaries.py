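"""Hierarchies, completeness, pathway tallies, KEGG URLs and
hypergeometric enrichment (with an exact combinatorial oracle)."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from prokann.summaries import (
    build_hierarchy,
    completeness,
    enrich,
    kegg_highlight_url,
    pathway_counts,
    round_half_away,
)


class TestBuildHierarchy:
    def test_single_gene_single_path(self):
        root = build_hierarchy({"g1": [["Metabolism", "Energy"]]}, "root")
        assert root.count == 1
        assert root.child("Metabolism").count == 1
        assert root.child("Metabolism").child("Energy").count == 1

    def test_multi_path_gene_counted_once_per_node(self):
        root = build_hierarchy(
            {"g1": [["Metabolism", "Energy"], ["Metabolism", "Carbon"]]}, "root"
        )
        assert root.count == 1
        assert root.child("Metabolism").count == 1
        assert root.child("Metabolism").child("Energy").count == 1
        assert root.child("Metabolism").child("Carbon").count == 1

    def test_disjoint_paths_sum_at_root(self):
        root = build_hierarchy({"g1": [["A"]], "g2": [["B"]]}, "root")
        assert root.count == 2
        assert [c.name for c in root.children] == ["A", "B"]

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            build_hierarchy({"g1": [[]]}, "root")

    @pytest.mark.parametrize("seed", range(5))
    def test_root_count_equals_distinct_annotated_genes(self, seed):
        rng = np.random.default_rng(seed)
        levels = [["A", "B"], ["x", "y", "z"]]
        assignments = {}
        for i in range(int(rng.integers(1, 40))):
            n_paths = int(rng.integers(1, 4))
            assignments[f"g{i}"] = [
                [levels[0][int(rng.integers(0, 2))], levels[1][int(rng.integers(0, 3))]]
                for _ in range(n_paths)
            ]
        root = build_hierarchy(assignments, "root")
        assert root.count == len(assignments)
        for child in root.children:
            assert root.count >= child.count


class TestCompleteness:
    def test_all_core_observed(self):
        rep = completeness({"COG1", "COG2", "COG3", "COG4"}, ["COG1", "COG2", "COG3", "COG4"], "bacteria")
        assert rep.completeness_pct == 100.00
        assert rep.core_observed == 4

    def test_three_of_four(self):
        rep = completeness({"COG1", "COG2", "COG3", "COG9"}, ["COG1", "COG2", "COG3", "COG4"], "bacteria")
        assert rep.completeness_pct == 75.00

    def test_none_observed(self):
        rep = completeness(set(), ["COG1", "COG2"], "archaea")
        assert rep.completeness_pct == 0.00

    def test_empty_core_list_rejected(self):
        with pytest.raises(ValueError):
            completeness({"COG1"}, [], "bacteria")

    def test_duplicate_core_list_rejected(self):
        with pytest.raises(ValueError):
            completeness({"COG1"}, ["COG1", "COG1"], "bacteria")


class TestPathwayCounts:
    def test_gene_counted_once_per_pathway(self):
        rows = pathway_counts(
            {"g1": ["K1", "K2"]},
            {"K1": [("map00010", "Glycolysis")], "K2": [("map00010", "Glycolysis")]},
        )
        assert rows == [("map00010", "Glycolysis", 1)]

    def test_equal_counts_ordered_alphabetically(self):
        rows = pathway_counts(
            {"g1": ["K1"], "g2": ["K2"]},
            {"K1": [("map00020", "Citrate cycle")], "K2": [("map00010", "ABC transporters")]},
        )
        assert [r[1] for r in rows] == ["ABC transporters", "Citrate cycle"]

    def test_empty_input(self):
        assert pathway_counts({}, {}) == []

    def test_multi_membership_total_inequality(self):
        gene_to_kos = {"g1": ["K1"], "g2": ["K2"], "g3": ["K3"]}
        ko_map = {
            "K1": [("map1", "P1"), ("map2", "P2")],
            "K2": [("map1", "P1")],
            "K3": [("map2", "P2")],
        }
        rows = pathway_counts(gene_to_kos, ko_map)
        assert sum(r[2] for r in rows) >= 3


class TestKeggUrl:
    def test_url_contains_endpoint_map_and_ko(self):
        url = kegg_highlight_url("map00362", ["K04100"])
        assert "show_pathway" in url and "00362" in url and "K04100" in url

    def test_duplicate_kos_collapse(self):
        url = kegg_highlight_url("map00362", ["K04100", "K04100"])
        assert url.count("K04100") == 1

    def test_empty_ko_list_plain_url(self):
        assert kegg_highlight_url("ko00010", []).endswith("?ko00010")

    def test_malformed_pathway_id_rejected(self):
        with pytest.raises(ValueError):
            kegg_highlight_url("pathway10", ["K00001"])

    def test_canonical_ordering(self):
        assert kegg_highlight_url("map00010", ["K2", "K1"]) == kegg_highlight_url(
            "map00010", ["K1", "K2"]
        )


def exact_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Closed-form upper tail P[X >= k], exact rational arithmetic."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)), total
    )


def enrichment_maps(N, K, n, k):
    """Background of N genes (first K carry term T); list with k carriers."""
    bg = {f"b{i}": ({"T"} if i < K else set()) for i in range(N)}
    listed = [f"b{i}" for i in range(k)] + [f"b{K + i}" for i in range(n - k)]
    return {g: bg[g] for g in listed}, bg


class TestEnrich:
    def test_worked_example_exact(self):
        listed, bg = enrichment_maps(20, 5, 5, 3)
        (res,) = enrich(listed, bg)
        assert res.p_value == pytest.approx(float(Fraction(1126, 15504)), abs=1e-12)
        assert (res.k, res.n, res.K, res.N) == (3, 5, 5, 20)

    def test_certain_event_has_p_one(self):
        listed, bg = enrichment_maps(8, 8, 8, 8)
        (res,) = enrich(listed, bg)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_bonferroni_multiplies_and_caps(self):
        # 10 terms; term T0 is carried by 3 of 3 list genes out of 3/12 in background
        bg = {f"b{i}": set() for i in range(12)}
        for i in range(3):
            bg[f"b{i}"].add("T0")
        for j in range(1, 10):
            bg[f"b{j}"].add(f"T{j}")
        listed = {f"b{i}": bg[f"b{i}"] for i in range(3)}
        results = enrich(listed, bg, method="bonferroni")
        m = len(results)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * m), abs=1e-12)

    def test_bh_bounded_and_order_invariant(self):
        rng = np.random.default_rng(2)
        bg = {
            f"b{i}": {f"T{int(rng.integers(0, 6))}", f"T{int(rng.integers(0, 6))}"}
            for i in range(30)
        }
        listed_keys = [f"b{i}" for i in range(10)]
        listed = {g: bg[g] for g in listed_keys}
        res = enrich(listed, bg, method="bh")
        shuffled = {g: bg[g] for g in reversed(listed_keys)}
        res2 = enrich(shuffled, bg, method="bh")
        assert [(r.term, r.p_adjusted) for r in res] == [(r.term, r.p_adjusted) for r in res2]
        for r in res:
            assert 0 <= r.p_value <= r.p_adjusted <= 1 + 1e-12

    def test_list_gene_absent_from_background_is_error(self):
        with pytest.raises(ValueError):
            enrich({"missing": {"T"}}, {"b1": {"T"}})

    def test_zero_count_terms_skipped(self):
        bg = {"b1": {"T1"}, "b2": {"T2"}, "b3": set()}
        res = enrich({"b1": bg["b1"]}, bg)
        assert [r.term for r in res] == ["T1"]

    def test_tail_matches_exhaustive_enumeration_small_populations(self):
        """Upper-tail probabilities equal brute-force enumeration of draws."""
        rng = np.random.default_rng(0)
        cases = []
        for N in range(2, 13):
            for _ in range(4):
                K = int(rng.integers(1, N + 1))
                n = int(rng.integers(1, N + 1))
                k_max = min(n, K)
                k = int(rng.integers(1, k_max + 1))
                if n - k <= N - K:
                    cases.append((N, K, n, k))
        assert len(cases) >= 30
        for N, K, n, k in cases:
            # enumeration over all C(N, n) draws
            carriers = set(range(K))
            favourable = sum(
                1
                for draw in itertools.combinations(range(N), n)
                if len(carriers.intersection(draw)) >= k
            )
            expected = Fraction(favourable, comb(N, n))
            listed, bg = enrichment_maps(N, K, n, k)
            res = {r.term: r for r in enrich(listed, bg)}
            assert res["T"].p_value == pytest.approx(float(expected), abs=1e-12), (N, K, n, k)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(87.195, 87.20), (1.985, 1.99), (0.205, 0.21), (5.314, 5.31), (-2.005, -2.01)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected
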