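"""Overlap enrichment statistics against enumeration oracles and worked values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ibdgba.overlap import (
    DomainError,
    bh_adjust,
    contingency,
    enrichment_ratio,
    exclusive_intersections,
    fisher_two_sided,
    hypergeom_upper,
    odds_ratio_ci,
    pairwise_overlap,
)


# ---------------------------------------------------------------------------
# oracles: exact integer enumeration over all tables with fixed margins
# ---------------------------------------------------------------------------

def enum_fisher_two_sided(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration (point-probability rule
    with the 1e-7 relative tie tolerance applied in exact arithmetic)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    obs = nums[a]
    total = sum(v for v in nums.values() if v * 10**7 <= obs * (10**7 + 1))
    return total / math.comb(n, r1)


def enum_hypergeom_upper(n_a, n_b, overlap, n):
    nums = [
        math.comb(n_b, k) * math.comb(n - n_b, n_a - k)
        for k in range(overlap, min(n_a, n_b) + 1)
    ]
    return sum(nums) / math.comb(n, n_a)


class TestContingency:
    def test_worked_example_from_printed_set_sizes(self):
        t = contingency(1029, 1062, 106, 20000)
        assert t.cells() == (106, 923, 956, 18015)

    def test_full_overlap(self):
        assert contingency(5, 5, 5, 20).cells() == (5, 0, 0, 15)

    def test_overlap_exceeding_set_size_is_domain_error(self):
        with pytest.raises(DomainError, match="overlap"):
            contingency(5, 5, 6, 20)

    def test_union_exceeding_background_is_domain_error(self):
        with pytest.raises(DomainError, match="background"):
            contingency(15, 10, 0, 20)


class TestOddsRatio:
    def test_published_ibd_asd_or(self):
        or_, lo, hi = odds_ratio_ci(contingency(1029, 1062, 106, 20000))
        assert round(or_, 2) == 2.16
        assert lo <= or_ <= hi

    def test_overlap_at_expectation_gives_or_one(self):
        # ad = bc: (2, 4, 4, 8)
        or_, _, _ = odds_ratio_ci(contingency(6, 6, 2, 18))
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        or_, lo, hi = odds_ratio_ci(contingency(10, 10, 0, 100))
        # corrected cells (0.5, 10.5, 10.5, 80.5)
        expected = (0.5 * 80.5) / (10.5 * 10.5)
        assert or_ == pytest.approx(expected)
        assert np.isfinite([or_, lo, hi]).all()


class TestFisherTwoSided:
    def test_degenerate_margin_gives_p_one(self):
        assert fisher_two_sided(contingency(0, 5, 0, 10)) == 1.0

    def test_small_table_matches_enumeration(self):
        t = contingency(10, 12, 1, 24)  # cells (1, 9, 11, 3)
        assert fisher_two_sided(t) == pytest.approx(enum_fisher_two_sided(1, 9, 11, 3), rel=1e-9)

    def test_large_table_significant_and_matches_scipy(self):
        t = contingency(1029, 1062, 106, 20000)
        p = fisher_two_sided(t)
        assert p < 0.05
        assert p == pytest.approx(stats.fisher_exact([[106, 923], [956, 18015]])[1], rel=1e-6)


class TestHypergeomUpper:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper(5, 5, 0, 20) == 1.0

    def test_small_case_matches_direct_summation(self):
        assert hypergeom_upper(5, 5, 3, 20) == pytest.approx(
            enum_hypergeom_upper(5, 5, 3, 20), rel=1e-12
        )

    def test_maximal_overlap_is_point_mass(self):
        p = hypergeom_upper(5, 8, 5, 20)
        assert p == pytest.approx(math.comb(8, 5) / math.comb(20, 5), rel=1e-12)


def test_exhaustive_oracle_agreement_small_backgrounds():
    """Fisher two-sided and hypergeometric upper tail match exact integer
    enumeration for every distinct-margin table with N <= 40 (symmetry in the
    margins removes transposed/row-swapped duplicates)."""
    for n in range(1, 41):
        for r1 in range(0, n // 2 + 1):
            for c1 in range(0, r1 + 1):
                lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                for a in range(lo, hi + 1):
                    b, c, d = r1 - a, c1 - a, n - r1 - c1 + a
                    t = contingency(r1, c1, a, n)
                    assert fisher_two_sided(t) == pytest.approx(
                        enum_fisher_two_sided(a, b, c, d), rel=1e-9
                    ), (a, b, c, d)
                    assert hypergeom_upper(r1, c1, a, n) == pytest.approx(
                        enum_hypergeom_upper(r1, c1, a, n), rel=1e-9
                    ), (a, b, c, d)


class TestEnrichmentRatio:
    def test_published_ibd_asd_ratio(self):
        _, ratio = enrichment_ratio(1029, 1062, 106, 20000)
        assert round(ratio, 2) == 1.94

    def test_published_ibd_scz_expected(self):
        expected, _ = enrichment_ratio(1029, 3193, 238, 20000)
        assert round(expected) == 164

    def test_overlap_equal_to_expected_gives_ratio_one(self):
        expected, ratio = enrichment_ratio(100, 200, 1, 20000)
        assert expected == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_zero_expected_is_domain_error(self):
        with pytest.raises(DomainError):
            enrichment_ratio(0, 10, 0, 100)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_p_is_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, -0.1])
        with pytest.raises(DomainError):
            bh_adjust([1.5])

    def test_underflowed_zero_p_is_accepted(self):
        assert bh_adjust([0.5, 0.0]) == pytest.approx([0.5, 0.0])

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=25)
        expected = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=20))
    def test_never_decreases_and_permutation_invariant(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        perm = list(reversed(range(len(ps))))
        q_perm = bh_adjust([ps[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], rel=1e-12)

    def test_naive_step_up_oracle_on_random_vectors(self):
        """q_i = min over ranks >= rank(i) of p_(j)*m/j, computed naively."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 21))
            p = rng.uniform(1e-8, 1, size=n)
            order = np.argsort(p, kind="mergesort")
            expected = np.empty(n)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
                ]
                expected[idx] = min(1.0, min(candidates))
            assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)


class TestPairwiseOverlap:
    def test_five_sets_give_ten_results(self):
        sets = {f"S{i}": set(range(i, i + 10)) for i in range(5)}
        assert len(pairwise_overlap(sets, 1000)) == 10

    def test_duplicated_set_ratio_is_background_over_size(self):
        s = set(range(50))
        (res,) = pairwise_overlap({"A": s, "B": set(s)}, 1000)
        assert res.enrichment_ratio == pytest.approx(1000 / 50)

    def test_disjoint_sets_covering_background_have_or_below_one(self):
        (res,) = pairwise_overlap({"A": set(range(50)), "B": set(range(50, 100))}, 100)
        assert res.odds_ratio < 1.0

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(3)
        sets = {f"S{i}": set(rng.choice(500, size=60, replace=False)) for i in range(4)}
        for res in pairwise_overlap(sets, 1000):
            assert res.p_adjusted >= res.fisher_p - 1e-15

    def test_set_larger_than_background_is_domain_error(self):
        with pytest.raises(DomainError):
            pairwise_overlap({"A": set(range(30)), "B": set(range(5))}, 20)


class TestExclusiveIntersections:
    def test_three_element_case(self):
        out = exclusive_intersections({"A": {1, 2}, "B": {2, 3}})
        assert out == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_disjoint_sets_omit_empty_region(self):
        out = exclusive_intersections({"A": {1}, "B": {2}})
        assert ("A", "B") not in out

    def test_seeded_random_sets_match_membership_oracle(self):
        rng = np.random.default_rng(7)
        sets = {
            name: set(map(int, rng.choice(1000, size=100, replace=False)))
            for name in ("A", "B", "C")
        }
        out = exclusive_intersections(sets)
        # oracle: tabulate each element's exact membership signature
        from collections import Counter

        signatures = Counter()
        for el in set().union(*sets.values()):
            sig = tuple(name for name in sets if el in sets[name])
            signatures[sig] += 1
        assert out == dict(signatures)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.sets(st.integers(0, 30)),
            min_size=1,
            max_size=4,
        )
    )
    def test_region_counts_sum_to_union(self, sets):
        out = exclusive_intersections(sets)
        assert sum(out.values()) == len(set().union(*sets.values()))
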