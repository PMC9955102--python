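"""Bandt–Pompe core: patterns, ranks, entropy, missing patterns."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordicp import (
    EmbeddingConfig,
    PatternDistribution,
    distribution,
    missing_patterns,
    pattern_of,
    permutation_entropy,
    rank_of,
    symbolize,
    unrank,
)
from conftest import brute_force_symbolize


class TestPatternOf:
    @pytest.mark.parametrize(
        "window, digits",
        [
            ((3, 6, 8), (1, 2, 3)),
            ((8, 9, 5), (3, 1, 2)),
            ((9, 5, 10), (2, 1, 3)),
            ((5, 10, 2), (3, 1, 2)),
            ((5, 5, 7), (1, 2, 3)),  # tie: earlier index first
            ((7, 5, 5), (2, 3, 1)),
        ],
    )
    def test_examples(self, window, digits):
        assert pattern_of(window).digits == digits

    def test_pattern_knows_its_rank(self):
        p = pattern_of((8, 9, 5))
        assert (p.m, str(p), p.rank) == (3, "312", 5)


class TestRanking:
    @pytest.mark.parametrize(
        "digits, rank",
        [((1, 2, 3), 1), ((3, 2, 1), 6), ((3, 1, 2), 5), ((2, 1, 3), 3)],
    )
    def test_lexicographic_rank(self, digits, rank):
        assert rank_of(digits) == rank

    def test_matches_enumerated_lexicographic_order(self):
        for m in (2, 3, 4):
            for i, perm in enumerate(sorted(itertools.permutations(range(1, m + 1)))):
                assert rank_of(perm) == i + 1

    def test_endpoints(self):
        for m in range(2, 8):
            assert rank_of(tuple(range(1, m + 1))) == 1
            assert rank_of(tuple(range(m, 0, -1))) == math.factorial(m)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=2, max_value=7), st.data())
    def test_unrank_is_inverse(self, m, data):
        rank = data.draw(st.integers(min_value=1, max_value=math.factorial(m)))
        assert rank_of(unrank(rank, m)) == rank

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            rank_of((1, 1, 2))
        with pytest.raises(ValueError):
            rank_of((0, 1, 2))


class TestSymbolize:
    def test_worked_example(self, worked_series):
        ranks = symbolize(worked_series, EmbeddingConfig(m=3, tau=1))
        assert ranks.size == 5  # T - (m-1)*tau = 7 - 2
        assert ranks.tolist() == [1, 1, 5, 3, 5]

    def test_monotone_series_is_all_ascending(self):
        ranks = symbolize(np.arange(50.0), EmbeddingConfig(m=4, tau=1))
        assert (ranks == 1).all()

    def test_too_short_strict_raises(self):
        with pytest.raises(ValueError, match="too short"):
            symbolize([1.0, 2.0], EmbeddingConfig(m=3))

    def test_too_short_lenient_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = symbolize([1.0, 2.0], EmbeddingConfig(m=3), strict=False)
        assert out.size == 0

    def test_delay_subsampling(self):
        # tau=2 embeds (x_t, x_{t+2}, x_{t+4})
        x = [0, 9, 1, 8, 2, 7, 3]
        got = symbolize(x, EmbeddingConfig(m=3, tau=2))
        want = brute_force_symbolize(x, 3, tau=2)
        assert got.tolist() == want

    @settings(derandomize=True, max_examples=150)
    @given(
        st.integers(min_value=2, max_value=3),
        st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=10),
    )
    def test_agrees_with_brute_force(self, m, values):
        got = symbolize(values, EmbeddingConfig(m=m), strict=False)
        assert got.tolist() == brute_force_symbolize(values, m)


class TestDistribution:
    def test_worked_example_probabilities(self, worked_series):
        ranks = symbolize(worked_series, EmbeddingConfig(m=3))
        dist = distribution(ranks, m=3)
        # counts (2, 1, 2) over 5 vectors at lex ranks 1, 3, 5
        assert dist.counts.tolist() == [2, 0, 1, 0, 2, 0]
        np.testing.assert_allclose(dist.probs, [0.4, 0, 0.2, 0, 0.4, 0])
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_coverage(self):
        dist = distribution(np.arange(1, 721), m=6)
        np.testing.assert_allclose(dist.probs, 1 / 720)

    def test_degenerate_single_pattern(self):
        dist = distribution([1] * 10, m=3)
        assert dist.prob_of_rank(1) == 1.0
        assert dist.probs[1:].sum() == 0.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            distribution([], m=3)
        with pytest.raises(ValueError):
            distribution([7], m=3)


class TestPermutationEntropy:
    def test_limits(self):
        uniform = distribution(np.arange(1, 25), m=4)
        assert permutation_entropy(uniform) == pytest.approx(1.0, abs=1e-12)
        single = distribution([5] * 8, m=3)
        assert permutation_entropy(single) == 0.0

    def test_worked_example_value(self, worked_series):
        # hand-calculator oracle: -(2*0.4*ln0.4 + 0.2*ln0.2) / ln6 = 0.588763
        dist = distribution(symbolize(worked_series, EmbeddingConfig(m=3)), m=3)
        assert permutation_entropy(dist) == pytest.approx(0.58876, abs=1e-4)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                    min_size=4, max_size=200))
    def test_bounded_in_unit_interval(self, values):
        dist = distribution(symbolize(values, EmbeddingConfig(m=3)), m=3)
        assert 0.0 <= permutation_entropy(dist) <= 1.0

    def test_monotone_series_has_zero_entropy(self):
        for x in (np.arange(100.0), -np.arange(100.0)):
            dist = distribution(symbolize(x, EmbeddingConfig(m=5)), m=5)
            assert permutation_entropy(dist) == 0.0

    def test_iid_noise_approaches_one(self, rng):
        x = rng.uniform(size=200_000)
        dist = distribution(symbolize(x, EmbeddingConfig(m=3)), m=3)
        assert permutation_entropy(dist) > 0.999

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_invariant_under_pattern_relabeling(self, ranks, rnd):
        """PE and NMP depend only on the multiset of probabilities."""
        dist = distribution(ranks, m=3)
        perm = list(range(1, 7))
        rnd.shuffle(perm)
        relabeled = distribution([perm[r - 1] for r in ranks], m=3)
        assert permutation_entropy(relabeled) == pytest.approx(permutation_entropy(dist), abs=1e-12)
        assert missing_patterns(relabeled) == missing_patterns(dist)


class TestMissingPatterns:
    def test_worked_example(self, worked_series):
        """The five embedded vectors realize {123, 213, 312}; the three
        patterns 132, 231 and 321 never occur."""
        dist = distribution(symbolize(worked_series, EmbeddingConfig(m=3)), m=3)
        count, norm = missing_patterns(dist)
        assert count == 3
        assert norm == pytest.approx(3 / 6)
        missing_ranks = {r for r in range(1, 7) if dist.counts[r - 1] == 0}
        assert {str(unrank(r, 3)) for r in missing_ranks} == {"132", "231", "321"}

    def test_full_coverage_has_none(self):
        count, norm = missing_patterns(distribution(np.arange(1, 7), m=3))
        assert (count, norm) == (0, 0.0)

    def test_nonincreasing_as_series_extends(self, rng):
        x = rng.normal(size=400)
        cfg = EmbeddingConfig(m=3)
        prev = math.inf
        for T in range(10, 401, 30):
            dist = distribution(symbolize(x[:T], cfg), m=3)
            count, _ = missing_patterns(dist)
            assert count <= prev
            prev = count
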