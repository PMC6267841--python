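"""Exact imbalance distribution of incomplete permuted blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mctrial import (
    BlockScheme,
    enumerate_block_tuples,
    expected_imbalance,
    imbalance_distribution,
    max_expected_imbalance,
    mean_expected_imbalance,
    random_block_sequence,
)
from .conftest import pmf_by_enumeration


class TestBlockScheme:
    def test_complete_block_counts_follow_allocation_ratio(self):
        s = BlockScheme(6, 2)
        assert (s.n_arm1, s.n_arm2) == (4, 2)
        assert s.max_imbalance == 4.0

    @pytest.mark.parametrize("b,k", [(5, 1), (7, 2), (6, 4), (0, 1), (6, 0)])
    def test_invalid_schemes_rejected(self, b, k):
        with pytest.raises(ValueError):
            BlockScheme(b, k)


class TestEnumeration:
    def test_minimal_balanced_block(self):
        assert set(enumerate_block_tuples(BlockScheme(2, 1))) == {(1, 2), (2, 1)}

    def test_two_to_one_allocation_block(self):
        assert set(enumerate_block_tuples(BlockScheme(3, 2))) == {
            (1, 1, 2),
            (1, 2, 1),
            (2, 1, 1),
        }

    @pytest.mark.parametrize("b,k", [(4, 1), (6, 1), (6, 2), (8, 3)])
    def test_cardinality_is_binomial_coefficient(self, b, k):
        tuples = enumerate_block_tuples(BlockScheme(b, k))
        assert len(tuples) == math.comb(b, b // (k + 1))
        assert len(set(tuples)) == len(tuples)
        assert all(t.count(1) == k * b // (k + 1) for t in tuples)

    def test_large_blocks_directed_to_hypergeometric_path(self):
        with pytest.raises(ValueError, match="hypergeometric"):
            enumerate_block_tuples(BlockScheme(22, 1))


class TestImbalanceDistribution:
    @pytest.mark.parametrize(
        "b,k,r,expected",
        [
            (6, 1, 6, {0.0: 1.0}),  # complete block: perfectly balanced
            (6, 1, 1, {1.0: 1.0}),  # a single subject always gives |delta| = 1
            (6, 1, 3, {1.0: 0.9, 9.0: 0.1}),
            (3, 2, 1, {0.25: 2 / 3, 1.0: 1 / 3}),
        ],
    )
    def test_exact_pmfs(self, b, k, r, expected):
        dist = imbalance_distribution(BlockScheme(b, k), r)
        got = dist.as_dict()
        assert sorted(got) == pytest.approx(sorted(expected), abs=1e-12)
        for ell, p in expected.items():
            assert got[ell] == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_oracle_on_small_blocks(self):
        for k in (1, 2, 3):
            for b in range(k + 1, 9, k + 1):
                for r in range(1, b + 1):
                    exact = {
                        round(s, 9): p
                        for s, p in imbalance_distribution(BlockScheme(b, k), r).as_dict().items()
                    }
                    oracle = pmf_by_enumeration(b, k, r)
                    assert set(exact) == set(oracle)
                    for ell, p in oracle.items():
                        assert exact[ell] == pytest.approx(p, abs=1e-12)

    def test_probabilities_sum_to_one_and_support_bounded(self):
        for b, k in [(6, 1), (8, 1), (9, 2), (12, 3)]:
            s = BlockScheme(b, k)
            for r in range(1, b + 1):
                dist = imbalance_distribution(s, r)
                assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
                assert (dist.support >= 0).all()
                assert (dist.support <= s.max_imbalance + 1e-9).all()

    @pytest.mark.parametrize("r", [0, -1, 7])
    def test_r_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            imbalance_distribution(BlockScheme(6, 1), r)


class TestExpectedImbalance:
    @pytest.mark.parametrize(
        "b,k,r,expected",
        [
            (6, 1, 6, 0.0),
            (6, 1, 3, 1.8),
            (8, 1, 4, 16 / 7),
        ],
    )
    def test_conditional_expectations(self, b, k, r, expected):
        assert expected_imbalance(BlockScheme(b, k), r) == pytest.approx(expected, abs=1e-12)

    @given(b_half=st.integers(1, 20), r=st.data())
    @settings(max_examples=60, deadline=None)
    def test_closed_form_for_balanced_allocation(self, b_half, r):
        b = 2 * b_half
        rv = r.draw(st.integers(1, b))
        assert expected_imbalance(BlockScheme(b, 1), rv) == pytest.approx(
            rv * (b - rv) / (b - 1), abs=1e-10
        )

    def test_symmetry_in_final_block_size(self):
        s = BlockScheme(10, 1)
        for r in range(1, 10):
            assert expected_imbalance(s, r) == pytest.approx(
                expected_imbalance(s, 10 - r), abs=1e-12
            )

    def test_maximised_at_half_block(self):
        s = BlockScheme(12, 1)
        values = [expected_imbalance(s, r) for r in range(1, 13)]
        assert int(np.argmax(values)) + 1 == 6


class TestSummaries:
    @pytest.mark.parametrize("b,expected", [(2, 0.5), (6, 7 / 6), (8, 1.5)])
    def test_mean_expected_imbalance(self, b, expected):
        assert mean_expected_imbalance(BlockScheme(b, 1)) == pytest.approx(expected, abs=1e-12)

    def test_mean_closed_form_for_balanced_allocation(self):
        for b in range(2, 42, 2):
            assert mean_expected_imbalance(BlockScheme(b, 1)) == pytest.approx(
                (b + 1) / 6, abs=1e-10
            )

    @pytest.mark.parametrize("b,expected", [(2, 1.0), (6, 1.8), (16, 64 / 15)])
    def test_max_expected_imbalance(self, b, expected):
        assert max_expected_imbalance(BlockScheme(b, 1)) == pytest.approx(expected, abs=1e-12)


class TestRandomBlockSequence:
    def test_complete_blocks_are_exactly_balanced(self):
        seq = random_block_sequence(BlockScheme(6, 1), 12, rng=7)
        assert len(seq) == 12
        assert (seq[:6] == 1).sum() == 3 and (seq[6:] == 1).sum() == 3

    def test_truncated_sequence_keeps_leading_blocks_complete(self):
        seq = random_block_sequence(BlockScheme(6, 1), 9, rng=11)
        assert len(seq) == 9
        assert (seq[:6] == 1).sum() == 3

    def test_two_to_one_ratio_in_complete_blocks(self):
        seq = random_block_sequence(BlockScheme(6, 2), 6, rng=3)
        assert (seq == 1).sum() == 4 and (seq == 2).sum() == 2

    def test_deterministic_under_fixed_seed(self):
        a = random_block_sequence(BlockScheme(8, 1), 20, rng=42)
        b = random_block_sequence(BlockScheme(8, 1), 20, rng=42)
        assert (a == b).all()

    def test_empirical_imbalance_matches_exact_pmf(self):
        # a 3-subject prefix of a permuted length-6 block: P(delta^2=9) = 0.1
        n_rep = 20_000
        rng = np.random.default_rng(515)
        hits = 0
        for _ in range(n_rep):
            seq = random_block_sequence(BlockScheme(6, 1), 3, rng=rng)
            j = int((seq == 1).sum())
            hits += (2 * j - 3) ** 2 == 9
        p_hat = hits / n_rep
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert abs(p_hat - 0.1) < 3 * se

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            random_block_sequence(BlockScheme(6, 1), 0)
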