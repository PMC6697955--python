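"""Distance/frequency scoring and candidate ranking."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from anatomap import (
    OccurrenceList,
    ScoringParams,
    combined_score,
    distance_score,
    distance_value,
    frequency_score,
    rank_candidates,
)
from anatomap.fixtures import generate_explanation, random_plant_spec
from anatomap.ontology import find_matches_in_text
from anatomap.oracle import brute_force_best


class TestDistanceValue:
    def test_mean_offset(self):
        assert distance_value(OccurrenceList("x", [3, 10])) == 6.5

    def test_first_offset(self):
        assert distance_value(OccurrenceList("x", [3, 10]), "first_offset") == 3

    def test_zero_offset(self):
        for mode in ("mean_offset", "first_offset"):
            assert distance_value(OccurrenceList("x", [0]), mode) == 0

    def test_matched_rank_needs_rank(self):
        occ = OccurrenceList("x", [5])
        assert distance_value(occ, "matched_rank", rank=2) == 2.0
        with pytest.raises(ValueError):
            distance_value(occ, "matched_rank")

    def test_empty_is_contract_violation(self):
        with pytest.raises(ValueError):
            distance_value(OccurrenceList("x", []))


class TestDistanceScore:
    def test_onset_scores_one(self):
        assert distance_score(0, 5) == 1.0

    def test_last_candidate_scores_zero(self):
        assert distance_score(8, 8) == pytest.approx(0.0, abs=1e-12)

    def test_halfway_is_cos_quarter_pi(self):
        assert distance_score(5, 10) == pytest.approx(math.cos(math.pi / 4), abs=1e-9)

    def test_degenerate_branches(self):
        assert distance_score(1, 1) == 1.0
        assert distance_score(0.3, 1) == 1.0
        assert distance_score(0, 0) == 0.0

    def test_d_above_maxd_is_contract_violation(self):
        with pytest.raises(ValueError):
            distance_score(3, 2)

    @given(
        maxD=st.floats(min_value=1.0001, max_value=1e6),
        frac=st.floats(min_value=0, max_value=1),
    )
    def test_range(self, maxD, frac):
        assert 0 <= distance_score(frac * maxD, maxD) <= 1

    @given(
        maxD=st.integers(min_value=2, max_value=10_000),
        d1=st.integers(min_value=0, max_value=10_000),
        d2=st.integers(min_value=0, max_value=10_000),
    )
    def test_strictly_decreasing_in_d(self, maxD, d1, d2):
        d1, d2 = sorted((d1 % (maxD + 1), d2 % (maxD + 1)))
        if d1 != d2:
            assert distance_score(d1, maxD) > distance_score(d2, maxD)


class TestFrequencyScore:
    def test_first_entity_boost(self):
        assert frequency_score(2, True) == 5.0

    def test_plain_count(self):
        assert frequency_score(3, False) == 3.0

    def test_zero(self):
        assert frequency_score(0, True) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            frequency_score(-1, False)


class TestCombinedScore:
    @pytest.mark.parametrize(
        "f_D,f_F,expected", [(1.0, 7.5, 22.5), (0, 1, 1.0), (0, 0, 0.0)]
    )
    def test_linear_combination(self, f_D, f_F, expected):
        assert combined_score(f_D, f_F, ScoringParams()) == expected


class TestRankCandidates:
    def test_empty_input(self):
        assert rank_candidates([], None, ScoringParams()) == []

    def test_single_candidate_is_first(self, onto):
        ranked = rank_candidates([OccurrenceList("heart", [4])], onto)
        assert len(ranked) == 1 and ranked[0].is_first

    def test_exactly_one_first_flag(self, onto):
        occs = [
            OccurrenceList("heart", [3, 9]),
            OccurrenceList("chest", [1]),
            OccurrenceList("lung", [6]),
        ]
        ranked = rank_candidates(occs, onto)
        assert sum(c.is_first for c in ranked) == 1
        assert next(c for c in ranked if c.is_first).part_id == "chest"

    def test_score_identity(self, onto):
        params = ScoringParams()
        for c in rank_candidates(
            [OccurrenceList("heart", [0, 4]), OccurrenceList("lung", [2, 8])],
            onto,
            params,
        ):
            assert c.score == pytest.approx(params.a * c.f_D + params.b * c.f_F)
            assert 0 <= c.f_D <= 1

    def test_electrocardiography_selects_heart(self, onto, kb_source):
        expl = kb_source.fetch("electrocardiography")
        ranked = rank_candidates(find_matches_in_text(onto, expl.tokens), onto)
        assert ranked[0].part_id == "heart"

    def test_exact_tie_breaks_to_deeper_node(self, onto):
        # "chest" (depth 0) and "heart" (depth 1) perfectly symmetric
        occs = [OccurrenceList("chest", [1]), OccurrenceList("heart", [1])]
        occs[0].offsets = [2]
        occs[1].offsets = [2]
        params = ScoringParams(first_multiplier=2.5)
        # both share D and F; only one carries the first-flag, so force a
        # tie by neutralizing the boost
        ranked = rank_candidates(occs, onto, ScoringParams(a=15, b=0))
        assert ranked[0].part_id == "heart"

    def test_frequency_monotonicity(self, onto):
        # raising a candidate's count (distance held fixed) never lowers it
        base = [OccurrenceList("heart", [0, 10]), OccurrenceList("lung", [4, 6])]
        ranked = rank_candidates(base, onto)
        pos = [c.part_id for c in ranked].index("lung")
        boosted = [
            OccurrenceList("heart", [0, 10]),
            OccurrenceList("lung", [4, 5, 6]),  # same mean distance, count +1
        ]
        ranked2 = rank_candidates(boosted, onto)
        assert [c.part_id for c in ranked2].index("lung") <= pos


def _oracle_check(onto, params, n_specs, seed):
    rng = random.Random(seed)
    agree = 0
    for _ in range(n_specs):
        spec = random_plant_spec(onto, rng)
        expl, _ = generate_explanation(spec, params, onto)
        occs = find_matches_in_text(onto, expl.tokens)
        ranked = rank_candidates(occs, onto, params)
        expected = brute_force_best(
            {o.part_id: list(o.offsets) for o in occs},
            depths={o.part_id: onto.depth(o.part_id) for o in occs},
            a=params.effective().a,
            b=params.effective().b,
            first_multiplier=params.first_multiplier,
            distance_mode=params.distance_mode,
            tie_break=params.tie_break,
        )
        agree += ranked[0].part_id == expected
    return agree


def test_ranker_matches_brute_force_oracle(onto):
    assert _oracle_check(onto, ScoringParams(), 300, seed=11) == 300


def test_distance_only_reduction_matches_oracle(onto):
    params = ScoringParams(algorithm="distance")
    assert _oracle_check(onto, params, 150, seed=12) == 150


def test_frequency_only_reduction_matches_oracle(onto):
    params = ScoringParams(algorithm="frequency")
    assert _oracle_check(onto, params, 150, seed=13) == 150


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ScoringParams(a=-1)
    with pytest.raises(ValueError):
        ScoringParams(distance_mode="median")
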