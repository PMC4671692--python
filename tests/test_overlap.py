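"""Representation factor, hypergeometric tail, Venn partitions, union summaries."""
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from convergene import (GeneSet, GeneUniverse, empirical_upper_tail,
                        gen_overlapping_sets, gen_universe, hypergeom_upper,
                        overlap, overlap_counts, permutation_null,
                        representation_factor, round_half_away, union_overlap,
                        venn_partition)
from convergene.errors import ContractError, UndefinedRFError


def hyper_upper_brute(N: int, K: int, n: int, k: int) -> float:
    """Direct combinatorial summation of the inclusive upper tail."""
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / comb(N, n)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (2.252, 2.3), (1.993, 2.0), (0.831, 0.8), (1.15, 1.2),
        (1.525, 1.5), (-2.25, -2.3), (0.974, 1.0),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected


class TestRepresentationFactor:
    @pytest.mark.parametrize("n_a,n_b,k,N,reported", [
        (85, 1035, 10, 19814, 2.3),
        (318, 2657, 85, 19814, 2.0),
        (12478, 6106, 3196, 19814, 0.8),
        (896, 2657, 141, 19814, 1.2),
        (70, 1035, 5, 19814, 1.4),
    ])
    def test_published_one_decimal_values(self, n_a, n_b, k, N, reported):
        assert round_half_away(representation_factor(n_a, n_b, k, N), 1) == reported

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_self_overlap_closed_form(self, n):
        # a list overlapped with itself: RF = N / n
        N = 20_000
        assert representation_factor(n, n, n, N) == pytest.approx(N / n)

    def test_zero_overlap_gives_zero(self):
        assert representation_factor(100, 100, 0, 1000) == 0.0

    def test_empty_list_is_undefined(self):
        with pytest.raises(UndefinedRFError):
            representation_factor(0, 100, 0, 1000)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ContractError):
            representation_factor(10, 10, 11, 1000)

    def test_rf_times_expected_recovers_k(self):
        for n_a, n_b, k, N in [(85, 1035, 10, 19814), (896, 2657, 141, 19814)]:
            rf = representation_factor(n_a, n_b, k, N)
            assert rf * (n_a * n_b / N) == pytest.approx(k)


class TestHypergeomUpper:
    def test_whole_support_is_one(self):
        assert hypergeom_upper(100, 30, 20, 0) == 1.0

    def test_single_term_tail_closed_form(self):
        assert hypergeom_upper(20, 10, 10, 10) == pytest.approx(1 / 184756, rel=1e-12)

    @pytest.mark.parametrize("k", range(6))
    def test_small_case_matches_enumeration(self, k):
        assert hypergeom_upper(10, 5, 5, k) == pytest.approx(
            hyper_upper_brute(10, 5, 5, k), abs=1e-14)

    def test_matches_bruteforce_on_grid(self):
        # exhaustive tail check across parameter grids up to N=100
        for N in (2, 3, 5, 10, 17, 33, 64, 100):
            step = max(1, N // 7)
            for K in range(0, N + 1, step):
                for n in range(0, N + 1, step):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert hypergeom_upper(N, K, n, k) == pytest.approx(
                            hyper_upper_brute(N, K, n, k), abs=1e-12), (N, K, n, k)

    def test_matches_one_sided_fisher(self):
        # same tail as Fisher's exact test on the equivalent 2x2 table
        for N in (5, 12, 25, 40, 60):
            step = max(1, N // 5)
            for K in range(1, N, step):
                for n in range(1, N, step):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        table = [[k, K - k], [n - k, N - K - n + k]]
                        _, p = fisher_exact(table, alternative="greater")
                        assert hypergeom_upper(N, K, n, k) == pytest.approx(p, rel=1e-9)

    def test_nonincreasing_in_k(self):
        N, K, n = 500, 60, 80
        tails = [hypergeom_upper(N, K, n, k) for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestOverlapSets:
    def test_identical_sets(self, small_universe):
        members = frozenset(sorted(small_universe.members)[:50])
        a = GeneSet(name="a", members=members)
        b = GeneSet(name="b", members=members)
        r = overlap(a, b, small_universe)
        assert r.k == 50
        assert r.rf == pytest.approx(small_universe.size / 50)

    def test_disjoint_sets(self, small_universe):
        pool = sorted(small_universe.members)
        a = GeneSet(name="a", members=frozenset(pool[:30]))
        b = GeneSet(name="b", members=frozenset(pool[30:60]))
        r = overlap(a, b, small_universe)
        assert (r.k, r.rf, r.p_upper) == (0, 0.0, 1.0)

    def test_planted_pair_recovers_rf(self):
        u = gen_universe(20_000, seed=3)
        sets, truth = gen_overlapping_sets(
            u, {"A": 500, "B": 400}, overlaps={("A", "B"): 50}, seed=3)
        r = overlap(sets["A"], sets["B"], u)
        assert r.k == 50 == truth["pairs"]["A|B"]
        assert r.rf == pytest.approx(5.0)

    def test_empty_set_rejected(self, small_universe):
        a = GeneSet(name="a", members=frozenset({"G000001"}))
        with pytest.raises(UndefinedRFError):
            overlap(a, GeneSet(name="b", members=frozenset(), n_raw=0), small_universe)


class TestVennPartition:
    def test_two_set_regions(self):
        a = GeneSet(name="A", members=frozenset({"1", "2"}))
        b = GeneSet(name="B", members=frozenset({"2", "3"}))
        part = venn_partition([a, b])
        assert part.regions[frozenset({"A"})] == {"1"}
        assert part.regions[frozenset({"B"})] == {"3"}
        assert part.regions[frozenset({"A", "B"})] == {"2"}

    def test_three_identical_sets_only_triple_region(self):
        sets = [GeneSet(name=n, members=frozenset({"X", "Y"})) for n in "ABC"]
        part = venn_partition(sets)
        for sig, genes in part.regions.items():
            assert genes == ({"X", "Y"} if len(sig) == 3 else frozenset())

    def test_region_count_is_2m_minus_1(self, abc_sets):
        assert len(venn_partition(list(abc_sets)).regions) == 7

    def test_matches_per_gene_enumeration(self):
        u = gen_universe(500, seed=7)
        sets, _ = gen_overlapping_sets(
            u, {"A": 80, "B": 60, "C": 70},
            overlaps={("A", "B"): 20, ("A", "C"): 15, ("B", "C"): 10},
            triple=5, seed=7)
        part = venn_partition(list(sets.values()))
        # brute-force oracle: classify every gene by direct membership tests
        union = sets["A"].members | sets["B"].members | sets["C"].members
        expected = {}
        for g in union:
            sig = frozenset(n for n in sets if g in sets[n].members)
            expected.setdefault(sig, set()).add(g)
        for sig, genes in part.regions.items():
            assert genes == frozenset(expected.get(sig, set())), sig
        assert sum(len(g) for g in part.regions.values()) == len(union)

    def test_arity_limits(self, abc_sets):
        a, b, _ = abc_sets
        with pytest.raises(ContractError):
            venn_partition([a])
        with pytest.raises(ContractError):
            venn_partition([GeneSet(name=str(i), members=frozenset({"X"}))
                            for i in range(5)])


class TestUnionOverlap:
    @pytest.mark.parametrize("n_target,k,expected_pct", [
        (44, 15, 34.1), (23, 9, 39.1), (1035, 530, 51.2),
    ])
    def test_published_percentages(self, n_target, k, expected_pct):
        assert round_half_away(100 * k / n_target, 1) == expected_pct

    def test_union_and_percentage(self, small_universe):
        pool = sorted(small_universe.members)
        target = GeneSet(name="t", members=frozenset(pool[:40]))
        p1 = GeneSet(name="p1", members=frozenset(pool[:10]))
        p2 = GeneSet(name="p2", members=frozenset(pool[5:20]))
        r = union_overlap(target, [p1, p2], small_universe)
        assert r.k == 20 and r.n_b == 20
        # parts all inside target: percentage = 100 * |union| / |target|
        assert r.percent_of_target == 50.0

    def test_empty_parts_rejected(self, small_universe, abc_sets):
        with pytest.raises(ContractError):
            union_overlap(abc_sets[0], [], small_universe)


class TestPermutationNull:
    def test_mean_matches_expectation(self):
        ks = permutation_null(500, 400, 20_000, reps=1000, seed=11)
        expected = 500 * 400 / 20_000
        se = np.sqrt(expected) / np.sqrt(1000)  # ~Poisson scale
        assert abs(ks.mean() - expected) < 4 * se

    def test_tail_matches_analytic(self):
        ks = permutation_null(500, 400, 20_000, reps=2000, seed=12)
        for k_obs in (8, 10, 14):
            p = hypergeom_upper(20_000, 500, 400, k_obs)
            emp = empirical_upper_tail(ks, k_obs)
            se = np.sqrt(p * (1 - p) / 2000)
            assert abs(emp - p) < 3.5 * se + 1e-9

    def test_seed_reproducibility(self):
        a = permutation_null(50, 40, 500, reps=200, seed=5)
        b = permutation_null(50, 40, 500, reps=200, seed=5)
        assert np.array_equal(a, b)


class TestCountMode:
    @pytest.mark.parametrize("n_a,n_b,k,expected", [
        (12478, 6106, 3196, 0.8), (896, 2657, 141, 1.2), (70, 1035, 5, 1.4),
    ])
    def test_count_mode_reported_rf(self, n_a, n_b, k, expected):
        assert overlap_counts(n_a, n_b, k, 19814).rf_reported == expected
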