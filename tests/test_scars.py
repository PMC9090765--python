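"""Scar-score unit tests: worked examples, invariances, oracle equivalence."""

import numpy as np
import pytest

from parpomics.model import Segment, SegmentProfile
from parpomics.oracles import (
    lst_oracle,
    tai_oracle,
    wgii_oracle_perbase,
    wgii_oracle_segments,
)
from parpomics.scars import (
    lst_score,
    median_total_cn,
    score_profile,
    tai_score,
    weighted_gii,
)
from parpomics.simulate import random_profile, simulate_profile

from conftest import make_profile

MB = 1_000_000


class TestMedian:
    def test_length_weighted(self, toy_build):
        p = make_profile([("1", 1, 150 * MB, 1, 1), ("1", 150 * MB + 1, 200 * MB, 2, 2)])
        assert median_total_cn(p, toy_build) == 2

    def test_uniform(self, toy_build):
        p = make_profile([("1", 1, 100 * MB, 2, 1)])
        assert median_total_cn(p, toy_build) == 3

    def test_even_split_takes_lower(self, toy_build):
        p = make_profile([("1", 1, 100 * MB, 1, 1), ("1", 100 * MB + 1, 200 * MB, 2, 2)])
        assert median_total_cn(p, toy_build) == 2

    def test_empty_autosomal_profile_errors(self, toy_build):
        p = make_profile([("X", 1, 100, 1, 1)])
        with pytest.raises(ValueError, match="autosomal"):
            median_total_cn(p, toy_build)


class TestWgii:
    def test_flat_profile_zero(self, toy_build):
        p = make_profile([("1", 1, 200 * MB, 1, 1), ("2", 1, 200 * MB, 1, 1)])
        assert weighted_gii(p, toy_build) == 0.0

    def test_worked_example(self, toy_build):
        p = make_profile(
            [
                ("1", 1, 50 * MB, 1, 1),
                ("1", 50 * MB + 1, 100 * MB, 2, 2),
                ("2", 1, 100 * MB, 1, 1),
            ]
        )
        assert weighted_gii(p, toy_build) == pytest.approx(0.25)

    def test_refinement_invariance(self, toy_build):
        whole = make_profile([("1", 1, 100 * MB, 2, 1), ("2", 1, 80 * MB, 1, 1)])
        split = make_profile(
            [
                ("1", 1, 40 * MB, 2, 1),
                ("1", 40 * MB + 1, 100 * MB, 2, 1),
                ("2", 1, 80 * MB, 1, 1),
            ]
        )
        assert weighted_gii(split, toy_build) == pytest.approx(
            weighted_gii(whole, toy_build)
        )
        assert lst_score(split, toy_build) == lst_score(whole, toy_build)
        assert tai_score(split, toy_build) == tai_score(whole, toy_build)


class TestLst:
    def test_single_segment_chromosome(self, toy_build):
        p = make_profile([("1", 1, 100 * MB, 2, 1)])
        assert lst_score(p, toy_build) == 0

    def test_abutting_pair_counts_both(self, toy_build):
        p = make_profile(
            [("1", 1, 15 * MB, 1, 1), ("1", 15 * MB + 1, 30 * MB, 2, 1)]
        )
        assert lst_score(p, toy_build) == 2

    def test_four_mb_gap_disqualifies(self, toy_build):
        p = make_profile(
            [("1", 1, 15 * MB, 1, 1), ("1", 19 * MB + 1, 34 * MB, 2, 1)]
        )
        assert lst_score(p, toy_build) == 0

    def test_short_segments_dropped_entirely(self, toy_build):
        # a 2 Mb interloper is removed, letting its long flanks pair
        p = make_profile(
            [
                ("1", 1, 15 * MB, 1, 1),
                ("1", 15 * MB + 1, 17 * MB, 3, 3),
                ("1", 17 * MB + 1, 32 * MB, 2, 1),
            ]
        )
        assert lst_score(p, toy_build) == 2

    def test_surviving_middle_segment_blocks_pairing(self, toy_build):
        # a kept 5 Mb middle segment separates the two long segments
        p = make_profile(
            [
                ("1", 1, 15 * MB, 1, 1),
                ("1", 15 * MB + 1, 20 * MB, 3, 3),
                ("1", 20 * MB + 1, 35 * MB, 2, 1),
            ]
        )
        assert lst_score(p, toy_build) == 0

    def test_middle_segment_with_two_partners_counts_once(self, toy_build):
        p = make_profile(
            [
                ("1", 1, 15 * MB, 1, 1),
                ("1", 15 * MB + 1, 30 * MB, 2, 1),
                ("1", 30 * MB + 1, 45 * MB, 3, 1),
            ]
        )
        assert lst_score(p, toy_build) == 3

    def test_per_arm_mode_ignores_centromere_spanning_pairs(self, toy_build):
        # two long segments abutting exactly at the centromere boundary
        p = make_profile(
            [("1", 70 * MB, 95 * MB, 1, 1), ("1", 95 * MB + 1, 120 * MB, 2, 1)]
        )
        assert lst_score(p, toy_build) == 2
        assert lst_score(p, toy_build, per_arm=True) == 0


class TestTai:
    def test_balanced_profile_zero(self, toy_build):
        p = make_profile([("1", 1, 90 * MB, 1, 1), ("1", 100 * MB, 200 * MB, 2, 2)])
        assert tai_score(p, toy_build) == 0

    def test_q_terminal_run_before_centromere(self, toy_build):
        p = make_profile(
            [
                ("1", 1, 90 * MB, 1, 1),
                ("1", 100 * MB + 1, 150 * MB, 1, 1),
                ("1", 150 * MB + 1, 200 * MB, 2, 1),
            ]
        )
        assert tai_score(p, toy_build) == 1

    def test_acrocentric_p_arm_ignored(self, toy_build):
        # chromosome 3 of the toy build is acrocentric
        p = make_profile(
            [("3", 1, 40 * MB, 2, 1), ("3", 40 * MB + 1, 200 * MB, 1, 1)]
        )
        assert tai_score(p, toy_build) == 0
        same_on_1 = make_profile(
            [("1", 1, 40 * MB, 2, 1), ("1", 40 * MB + 1, 200 * MB, 1, 1)]
        )
        assert tai_score(same_on_1, toy_build) == 1

    def test_run_reaching_centromere_scores_zero(self, toy_build):
        p = make_profile(
            [("1", 1, 95 * MB, 2, 1), ("1", 95 * MB + 1, 200 * MB, 1, 1)]
        )
        assert tai_score(p, toy_build) == 0

    def test_whole_chromosome_imbalance_scores_zero(self, toy_build):
        p = make_profile([("1", 1, 200 * MB, 2, 1)])
        assert tai_score(p, toy_build) == 0


class TestOracleEquivalence:
    def test_lst_tai_match_oracles_on_random_profiles(self, toy_build):
        for seed in range(200):
            p = random_profile(toy_build, seed=seed)
            assert lst_score(p, toy_build) == lst_oracle(p, toy_build), seed
            assert tai_score(p, toy_build) == tai_oracle(p, toy_build), seed

    def test_wgii_matches_perbase_oracle_on_mini_build(self, mini_build):
        for seed in range(60):
            p = random_profile(mini_build, seed=seed, mean_breaks=4)
            assert weighted_gii(p, mini_build) == pytest.approx(
                wgii_oracle_perbase(p, mini_build)
            ), seed

    def test_wgii_segment_oracle_agrees_with_perbase(self, mini_build):
        for seed in range(30):
            p = random_profile(mini_build, seed=seed, mean_breaks=4)
            assert wgii_oracle_segments(p, mini_build) == pytest.approx(
                wgii_oracle_perbase(p, mini_build)
            )


class TestPlantedEvents:
    @pytest.mark.parametrize("n_pairs,n_tai", [(0, 0), (1, 0), (0, 1), (3, 2), (6, 5)])
    def test_planted_counts_recovered_exactly(self, toy_build, n_pairs, n_tai):
        profile, truth = simulate_profile(toy_build, n_pairs, n_tai, seed=11)
        assert lst_score(profile, toy_build) == 2 * n_pairs == truth.lst_truth
        assert tai_score(profile, toy_build) == n_tai == truth.tai_truth
        assert weighted_gii(profile, toy_build) == pytest.approx(truth.wgii_truth)

    def test_monotone_construction(self, toy_build):
        """One more planted pair adds exactly 2 LSTs; one more terminal
        imbalance run adds exactly 1 TAI."""
        for k in range(5):
            a, _ = simulate_profile(toy_build, k, 0, seed=3)
            b, _ = simulate_profile(toy_build, k + 1, 0, seed=3)
            assert lst_score(b, toy_build) - lst_score(a, toy_build) == 2
            c, _ = simulate_profile(toy_build, 0, k, seed=3)
            d, _ = simulate_profile(toy_build, 0, k + 1, seed=3)
            assert tai_score(d, toy_build) - tai_score(c, toy_build) == 1


def test_scores_independent_of_input_order(toy_build):
    segs = [
        Segment("1", 1, 15 * MB, 1, 1),
        Segment("1", 15 * MB + 1, 30 * MB, 2, 1),
        Segment("2", 1, 200 * MB, 2, 2),
    ]
    forward = SegmentProfile("f", list(segs))
    backward = SegmentProfile("b", list(reversed(segs)))
    sf, sb = score_profile(forward, toy_build), score_profile(backward, toy_build)
    assert (sf.wgii, sf.lst, sf.tai) == (sb.wgii, sb.lst, sb.tai)


def test_sex_chromosomes_excluded(toy_build):
    p = make_profile(
        [("1", 1, 200 * MB, 1, 1), ("X", 1, 30 * MB, 5, 0)]
    )
    s = score_profile(p, toy_build)
    assert (s.wgii, s.lst, s.tai) == (0.0, 0, 0)
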