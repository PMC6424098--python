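"""Overlap, capture-recapture FDR, hypergeometric/BH machinery, ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prisma_screen.enrichment_stats import (
    annotation_enrichment,
    bh_adjust,
    estimate_interaction_fdr,
    fisher_combine,
    hypergeometric_test,
    overlap_stats,
    rank_complexes,
)
from prisma_screen.screen_io import ComplexCatalog, ReferenceSet
from prisma_screen.synthetic_screen import simulate_replicate_overlap


def refset(name, members, role="reference_interactome"):
    return ReferenceSet(name, frozenset(members), role)


class TestOverlap:
    def test_directional_coverages(self):
        report = overlap_stats(refset("q", "abc"), refset("r", "bcd"))
        assert report.intersection == 2
        assert report.coverage_of_reference == pytest.approx(200 / 3)
        assert report.coverage_of_query == pytest.approx(200 / 3)

    def test_disjoint_sets(self):
        report = overlap_stats(refset("q", "ab"), refset("r", "cd"))
        assert report.intersection == 0
        assert report.coverage_of_reference == 0.0


class TestFDREstimator:
    def test_hand_computed_values(self):
        """FDR_A = 1 - |A∩B|·|R| / (|A|·|B∩R|), worked by hand."""
        a = refset("A", {f"a{i}" for i in range(20)} | {f"c{i}" for i in range(80)})
        b = refset("B", {f"b{i}" for i in range(20)} | {f"c{i}" for i in range(80)})
        r = refset("R", {f"c{i}" for i in range(40)} | {f"r{i}" for i in range(10)})
        est = estimate_interaction_fdr(a, b, r)
        # |A|=100, |A∩B|=80, |R|=50, |B∩R|=40 -> FDR = 1 - 80*50/(100*40) = 0
        assert (est.size_a, est.intersection_ab, est.size_r,
                est.intersection_br) == (100, 80, 50, 40)
        assert est.fdr == pytest.approx(0.0)

    def test_second_hand_computed_value(self):
        a = refset("A", {f"a{i}" for i in range(40)} | {f"c{i}" for i in range(60)})
        b = refset("B", {f"b{i}" for i in range(20)} | {f"c{i}" for i in range(60)})
        r = refset("R", {f"c{i}" for i in range(40)} | {f"r{i}" for i in range(10)})
        est = estimate_interaction_fdr(a, b, r)
        # |A|=100, |A∩B|=60, |R|=50, |B∩R|=40 -> 1 - 60*50/(100*40) = 0.25
        assert est.fdr == pytest.approx(0.25)

    def test_perfect_replication_limit(self):
        a = refset("A", {f"x{i}" for i in range(50)})
        r = refset("R", {f"x{i}" for i in range(20)})
        assert estimate_interaction_fdr(a, a, r).fdr == pytest.approx(0.0)

    def test_no_reference_overlap_not_evaluable(self):
        est = estimate_interaction_fdr(refset("A", "ab"), refset("B", "ab"),
                                       refset("R", "xy"))
        assert not est.evaluable and est.fdr is None

    @pytest.mark.parametrize("planted", [0.05, 0.15, 0.30])
    def test_monte_carlo_recovery(self, planted):
        """Mean estimate over 20 simulated screen pairs recovers the planted
        FDR within ±0.03 (capture-recapture assumptions hold exactly)."""
        estimates = []
        for seed in range(20):
            a, b, r, _ = simulate_replicate_overlap(planted, seed=seed)
            estimates.append(estimate_interaction_fdr(a, b, r).fdr)
        assert abs(np.mean(estimates) - planted) <= 0.03


def brute_force_upper_tail(k, n, big_k, big_n):
    """Exhaustive oracle: enumerate all n-subsets of a big_n universe."""
    universe = list(range(big_n))
    category = set(range(big_k))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(category.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_toy_case(self):
        """Drawing all 4 category members in 4 draws from 10: 1/C(10,4)."""
        assert hypergeometric_test(4, 4, 4, 10) == pytest.approx(1 / 210)

    def test_k_zero_is_one(self):
        assert hypergeometric_test(0, 0, 4, 10) == 1.0
        assert hypergeometric_test(0, 4, 0, 10) == 1.0
        assert hypergeometric_test(0, 3, 3, 10) == 1.0

    def test_matches_exhaustive_enumeration_small_universes(self):
        """Upper-tail p equals subset enumeration for every configuration
        with N <= 12."""
        for big_n in range(1, 13):
            for n in range(0, big_n + 1):
                for big_k in range(0, big_n + 1):
                    for k in range(0, min(n, big_k) + 1):
                        expected = brute_force_upper_tail(k, n, big_k, big_n)
                        assert hypergeometric_test(k, n, big_k, big_n) == (
                            pytest.approx(expected)
                        ), (k, n, big_k, big_n)

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            big_n = int(rng.integers(5, 2000))
            big_k = int(rng.integers(0, big_n + 1))
            n = int(rng.integers(0, big_n + 1))
            k = int(rng.integers(0, min(n, big_k) + 1))
            expected = stats.hypergeom.sf(k - 1, big_n, big_k, n)
            assert hypergeometric_test(k, n, big_k, big_n) == pytest.approx(
                expected, rel=1e-9, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(5, 4, 4, 10)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 4, 11, 10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        adjusted = np.array(bh_adjust(p))
        assert (adjusted >= p - 1e-12).all()
        assert (adjusted <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()  # monotone step-up

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 50)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(list(expected))

    def test_order_equivariant(self):
        p = [0.04, 0.001, 0.9, 0.04]
        perm = [2, 0, 3, 1]
        direct = bh_adjust([p[i] for i in perm])
        reference = bh_adjust(p)
        assert direct == pytest.approx([reference[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAnnotationEnrichment:
    def test_full_cover_term_significant(self):
        background = [f"g{i}" for i in range(10)]
        query = background[:4]
        frame = annotation_enrichment(query, {"term": background[:4]}, background)
        assert frame.loc[0, "p_value"] == pytest.approx(1 / 210)
        assert bool(frame.loc[0, "significant"])

    def test_empty_query_nothing_significant(self):
        background = [f"g{i}" for i in range(10)]
        frame = annotation_enrichment([], {"t1": background[:3]}, background)
        assert (frame["p_value"] == 1.0).all()
        assert not frame["significant"].any()

    def test_duplicate_members_deduplicated(self):
        background = [f"g{i}" for i in range(10)]
        frame = annotation_enrichment(
            background[:2], {"t": ["g0", "g0", "g1"]}, background)
        assert frame.loc[0, "term_size"] == 2

    def test_term_without_background_members_skipped(self):
        background = ["g0", "g1"]
        frame = annotation_enrichment(["g0"], {"ghost": ["zz"]}, background)
        assert len(frame) == 0

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            annotation_enrichment(["alien"], {}, ["g0"])


def toy_catalog():
    complexes = [
        ("1", "full", frozenset({"p0", "p1", "p2", "p3"})),
        ("2", "none", frozenset({"q0", "q1", "q2", "q3"})),
        ("3", "partial", frozenset({"p0", "p1", "q4", "q5"})),
        ("4", "pair", frozenset({"p0", "q4"})),
        ("5", "filler", frozenset({"q7", "q8", "q9"})),
    ]
    return ComplexCatalog(complexes)


class TestRankComplexes:
    prisma = refset("prisma", {"p0", "p1", "p2", "p3"})
    ip = refset("ip", {"p2", "p3", "q4"}, role="ip_dataset")

    def test_ranks_form_permutation(self):
        frame = rank_complexes(self.prisma, self.ip, toy_catalog())
        retained = frame[frame["retained"]]
        assert sorted(retained["rank"]) == list(range(1, len(retained) + 1))
        assert frame.loc[~frame["retained"], "rank"].isna().all()

    def test_fully_covered_complex_outranks_uncovered(self):
        frame = rank_complexes(self.prisma, self.ip, toy_catalog()).set_index(
            "complex_id")
        assert frame.loc["1", "rank"] == 1.0
        assert not frame.loc["2", "retained"]  # zero screen overlap

    def test_min_combined_excludes_two_overlap_complex(self):
        """A complex with only 2 members in screen ∪ IP fails the >= 3
        combined-overlap filter."""
        frame = rank_complexes(self.prisma, self.ip, toy_catalog()).set_index(
            "complex_id")
        assert frame.loc["4", "overlap_combined"] == 2
        assert not frame.loc["4", "retained"]
        relaxed = rank_complexes(self.prisma, self.ip, toy_catalog(),
                                 min_combined=2).set_index("complex_id")
        assert relaxed.loc["4", "retained"]

    def test_upper_quartile_boundary(self):
        """417 retained complexes put the upper-quartile boundary at rank
        floor(417/4) = 104."""
        rng = np.random.default_rng(3)
        prisma_members = {f"p{i}" for i in range(300)}
        ip_members = {f"p{i}" for i in range(150, 450)}
        pool = sorted(prisma_members | ip_members | {f"x{i}" for i in range(600)})
        complexes = []
        for cid in range(500):
            members = frozenset(rng.choice(pool, size=8, replace=False))
            complexes.append((f"{cid:04d}", f"c{cid}", members))
        catalog = ComplexCatalog(complexes)
        frame = rank_complexes(refset("prisma", prisma_members),
                               refset("ip", ip_members, role="ip_dataset"),
                               catalog)
        retained = frame[frame["retained"]]
        n = len(retained)
        boundary = n // 4
        assert retained["upper_quartile"].sum() == boundary
        assert 417 // 4 == 104  # the quartile rule at the published list size

    def test_added_overlap_never_worsens_coverage_rank(self):
        base = rank_complexes(self.prisma, self.ip, toy_catalog()).set_index(
            "complex_id")
        richer = refset("prisma", set(self.prisma.members) | {"q4", "q5"})
        improved = rank_complexes(richer, self.ip, toy_catalog()).set_index(
            "complex_id")
        assert (improved.loc["3", "coverage_prisma"]
                > base.loc["3", "coverage_prisma"])
        assert improved.loc["3", "rank_coverage"] <= base.loc["3", "rank_coverage"]

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            rank_complexes(self.prisma, self.ip, ComplexCatalog([]))


def test_fisher_combination_orders_jointly_small_pvalues_first():
    assert fisher_combine(0.01, 0.01) < fisher_combine(0.01, 0.5)
    assert fisher_combine(0.5, 0.5) < fisher_combine(1.0, 1.0) + 1e-12
    # agrees with scipy's implementation of Fisher's method
    expected = stats.combine_pvalues([0.03, 0.2], method="fisher")[1]
    assert fisher_combine(0.03, 0.2) == pytest.approx(expected)
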