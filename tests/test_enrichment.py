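"""Enrichment statistics: common-variant sets, contingency counts, fold,
exact test, intervals, FDR, and the composed per-group analysis."""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varenrich import (
    BackgroundCounts,
    CohortGroup,
    VariantKey,
    VEAConfig,
    bh_adjust,
    fisher_upper_p,
    fold_enrichment,
    group_common_variants,
    pathway_contingency,
    ratio_ci,
    run_vea,
)


def hypergeom_upper_oracle(a, n1, c, n2):
    """Brute-force enumeration of the hypergeometric upper tail P(X >= a)."""
    M, K, N = n1 + n2, a + c, n1
    return sum(comb(K, k) * comb(M - K, N - k) for k in range(a, min(K, N) + 1)) / comb(M, N)


def bh_stepup_oracle(p):
    """Step-up definition of Benjamini–Hochberg, written out directly."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestGroupCommonVariants:
    def test_intersection_rule(self, toy_group):
        assert group_common_variants(toy_group, rule="all") == [
            VariantKey("chr1", 100, "A", "G")
        ]

    def test_min_share_rule(self, toy_group):
        assert len(group_common_variants(toy_group, rule="min_share", k=2)) == 3
        assert len(group_common_variants(toy_group, rule="min_share", k=1)) == 3
        assert len(group_common_variants(toy_group, rule="min_share", k=3)) == 1

    def test_single_member_group_identity(self):
        v = VariantKey("chr1", 1, "A", "C")
        g = CohortGroup("X", ["S1"], {"S1": {v}}, {v: "G1"})
        assert group_common_variants(g, rule="all") == [v]

    def test_unknown_rule_rejected(self, toy_group):
        with pytest.raises(ValueError, match="rule"):
            group_common_variants(toy_group, rule="majority")

    def test_output_sorted_by_variant_key(self, toy_group):
        keys = group_common_variants(toy_group, rule="min_share", k=2)
        assert keys == sorted(keys)


class TestPathwayContingency:
    def test_hand_enumerated_counts(self, toy_db, toy_bg):
        # P1={G1,G2}, P2={G2,G3}; v3's gene G4 lies outside the universe
        common = {
            VariantKey("chr1", 1, "A", "C"): "G1",
            VariantKey("chr1", 2, "A", "C"): "G2",
            VariantKey("chr1", 3, "A", "C"): "G4",
        }
        rows = {r[0]: r for r in (tuple(x) for x in pathway_contingency(common, toy_db, toy_bg))}
        assert rows["P1"] == ("P1", 2, 2, 50, 1000)
        assert rows["P2"] == ("P2", 1, 2, 30, 1000)

    def test_all_denominator_counts_every_variant(self, toy_db, toy_bg):
        common = {
            VariantKey("chr1", 1, "A", "C"): "G1",
            VariantKey("chr1", 2, "A", "C"): "G2",
            VariantKey("chr1", 3, "A", "C"): "G4",
        }
        rows = pathway_contingency(common, toy_db, toy_bg, denominator="all")
        assert all(r[2] == 3 for r in rows)
        assert {r[0]: r[1] for r in rows} == {"P1": 2, "P2": 1}

    def test_empty_common_set(self, toy_db, toy_bg):
        rows = pathway_contingency({}, toy_db, toy_bg)
        assert all(r[1] == 0 and r[2] == 0 for r in rows)


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "a, n1, c, n2, expected",
        [
            (12, 5610, 69, 180208, 5.59),    # strong enrichment, small counts
            (151, 5610, 1847, 180208, 2.63), # ratio-of-ratios, not cross-product OR
            (5, 100, 10, 200, 1.0),
            (0, 100, 10, 200, 0.0),
        ],
    )
    def test_reference_values(self, a, n1, c, n2, expected):
        assert fold_enrichment(a, n1, c, n2) == pytest.approx(expected, abs=0.005)

    def test_distinct_from_cross_product_odds_ratio(self):
        # the cross-product OR of this table is 2.67; the enrichment ratio 2.63
        fold = fold_enrichment(151, 5610, 1847, 180208)
        assert round(fold, 2) == 2.63
        cross = (151 / (5610 - 151)) / (1847 / (180208 - 1847))
        assert round(cross, 2) == 2.67

    def test_undefined_for_zero_background(self):
        with pytest.raises(ValueError, match="undefined"):
            fold_enrichment(5, 100, 0, 200)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.integers(1, 50),
        extra1=st.integers(0, 50),
        c=st.integers(1, 500),
        extra2=st.integers(0, 500),
    )
    def test_reciprocal_symmetry(self, a, extra1, c, extra2):
        n1, n2 = a + extra1, c + extra2
        prod = fold_enrichment(a, n1, c, n2) * fold_enrichment(c, n2, a, n1)
        assert prod == pytest.approx(1.0, rel=1e-12)


class TestFisherUpperP:
    @pytest.mark.parametrize(
        "a, n1, c, n2, expected",
        [
            (2, 5, 2, 10, 1221 / 3003),  # enumerated over k = 0..4
            (0, 5, 2, 10, 1.0),
            (2, 2, 0, 3, 0.1),           # C(2,2)*C(3,0)/C(5,2)
        ],
    )
    def test_enumerated_values(self, a, n1, c, n2, expected):
        assert fisher_upper_p(a, n1, c, n2) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            fisher_upper_p(6, 5, 2, 10)

    @settings(derandomize=True, max_examples=200)
    @given(
        n1=st.integers(1, 25),
        n2=st.integers(1, 25),
        data=st.data(),
    )
    def test_matches_brute_force_enumeration(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        assert fisher_upper_p(a, n1, c, n2) == pytest.approx(
            hypergeom_upper_oracle(a, n1, c, n2), abs=1e-12
        )


class TestRatioCI:
    def test_katz_interval_reference_value(self):
        low, high = ratio_ci(12, 5610, 69, 180208)
        assert (low, high) == pytest.approx((3.03, 10.31), abs=0.005)

    def test_interval_brackets_fold(self):
        low, high = ratio_ci(25, 400, 300, 20000)
        fold = fold_enrichment(25, 400, 300, 20000)
        assert low <= fold <= high

    def test_null_interval_straddles_one(self):
        low, high = ratio_ci(50, 1000, 500, 10000)
        assert low < 1.0 < high

    def test_widens_monotonically_with_level(self):
        widths = []
        for level in (0.8, 0.9, 0.95, 0.99):
            low, high = ratio_ci(12, 5610, 69, 180208, level=level)
            widths.append(high - low)
        assert widths == sorted(widths)

    def test_conditional_method_reproduces_published_interval(self):
        # conditional exact interval of the (count, total) table matches the
        # published 95% CI for the strongly enriched MHC-downregulation row
        low, high = ratio_ci(12, 5610, 69, 180208, method="conditional")
        assert (low, high) == pytest.approx((2.75, 10.40), abs=0.02)

    def test_degenerate_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ratio_ci(0, 100, 10, 200)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05], [0.05]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_small_cases(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=100)
    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_stepup_definition_and_never_decreases(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_stepup_oracle(pvals), abs=1e-12)
        assert all(q >= p for q, p in zip(adj, pvals))
        # ranking of distinct p-values preserved
        for i in range(len(pvals)):
            for j in range(len(pvals)):
                if pvals[i] < pvals[j]:
                    assert adj[i] <= adj[j] + 1e-15


class TestRunVea:
    def test_published_counts_reproduce_fold_column(self):
        from varenrich.datasets import PUBLISHED_ENRICHMENT

        for row in PUBLISHED_ENRICHMENT:
            fold = fold_enrichment(row.a, row.n1, row.c, row.n2)
            assert fold == pytest.approx(row.or_printed, abs=0.011), row.pathway_id

    def test_toy_fixture_matches_hand_enumeration(self, toy_db, toy_bg):
        # common set after intersection: v1 (G1); P1 a=1, P2 a=0, n1=1
        v1 = VariantKey("chr1", 100, "A", "G")
        v2 = VariantKey("chr1", 200, "C", "G")
        group = CohortGroup(
            "TOY",
            ["S1", "S2"],
            {"S1": {v1, v2}, "S2": {v1}},
            {v1: "G1", v2: "G2"},
        )
        res = run_vea(group, toy_db, toy_bg)
        by_id = {r.pathway_id: r for r in res.records}
        r1 = by_id["P1"]
        assert (r1.a, r1.n1, r1.c, r1.n2) == (1, 1, 50, 1000)
        assert r1.fold == pytest.approx((1 / 1) / (50 / 1000))
        assert r1.p == pytest.approx(hypergeom_upper_oracle(1, 1, 50, 1000), abs=1e-12)
        r2 = by_id["P2"]
        assert (r2.a, r2.p) == (0, 1.0)
        assert r2.fold == 0.0
        # BH over the two tested pathways
        assert sorted([r1.adj_p, r2.adj_p]) == pytest.approx(
            sorted(bh_stepup_oracle([r1.p, r2.p]))
        )

    def test_zero_background_pathway_excluded(self, toy_db):
        bg = BackgroundCounts(per_pathway={"P1": 50, "P2": 0}, total=1000)
        v1 = VariantKey("chr1", 100, "A", "G")
        group = CohortGroup("TOY", ["S1"], {"S1": {v1}}, {v1: "G1"})
        res = run_vea(group, toy_db, bg)
        assert {r.pathway_id for r in res.records} == {"P1"}

    def test_empty_common_set_yields_empty_result(self, toy_db, toy_bg):
        v1, v2 = VariantKey("chr1", 1, "A", "C"), VariantKey("chr1", 2, "A", "C")
        group = CohortGroup(
            "TOY", ["S1", "S2"], {"S1": {v1}, "S2": {v2}}, {v1: "G1", v2: "G1"}
        )
        res = run_vea(group, toy_db, toy_bg)
        assert res.records == ()

    def test_records_sorted_by_adj_p_then_id(self, toy_db, toy_bg, toy_group):
        res = run_vea(toy_group, toy_db, toy_bg, VEAConfig(share_rule="min_share", min_share_k=1))
        keys = [(r.adj_p, r.pathway_id) for r in res.records]
        assert keys == sorted(keys)

    def test_two_sided_option(self, toy_db, toy_bg, toy_group):
        res1 = run_vea(toy_group, toy_db, toy_bg)
        res2 = run_vea(toy_group, toy_db, toy_bg, VEAConfig(two_sided=True))
        p1 = {r.pathway_id: r.p for r in res1.records}
        p2 = {r.pathway_id: r.p for r in res2.records}
        assert all(p2[pid] >= p1[pid] - 1e-12 for pid in p1)
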