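"""Worked scoring examples, policy modes, and engine/oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p3c_oct import (
    LikertRating,
    OrganisationResponse,
    QuestionResponse,
    ScoringError,
    ScoringPolicy,
    SubjectiveMode,
    UnansweredPolicy,
    objective_score,
    score_organisation,
    score_question,
    subjective_score,
)

from tests.helpers import (
    make_instrument,
    make_question,
    oracle_question_scores,
    random_instrument,
    random_response,
)


def eight_code_question():
    return make_question("Q1", [8])


def response(q, n_ticked=0, likert=LikertRating.UNANSWERED, ticked=None):
    if ticked is None:
        ordered = sorted(q.scoreable_ids)
        ticked = set(ordered[:n_ticked])
    return QuestionResponse(question_id=q.question_id, ticked_codes=ticked,
                            likert=likert)


class TestObjectiveScore:
    def test_one_of_eight_activities_scores_1_25(self):
        q = eight_code_question()
        assert objective_score(q, response(q, 1)) == pytest.approx(1.25)

    def test_full_activity_scores_10(self):
        q = eight_code_question()
        assert objective_score(q, response(q, 8)) == pytest.approx(10.0)

    def test_none_marker_scores_0(self):
        q = eight_code_question()
        r = response(q, ticked=set(q.none_ids))
        assert objective_score(q, r) == 0.0

    def test_multi_part_codes_pool_to_keep_max_10(self):
        # 6 + 4 scoreable codes across two parts: 5 ticks -> 5 * 10/10
        q = make_question("Q6", [6, 4])
        assert q.scoreable_count == 10
        assert objective_score(q, response(q, 5)) == pytest.approx(5.0)
        assert objective_score(q, response(q, 10)) == pytest.approx(10.0)

    def test_conflicting_ticks_never_scored_silently(self):
        q = eight_code_question()
        bad = set(list(q.scoreable_ids)[:1]) | q.none_ids
        with pytest.raises(ScoringError, match="conflict"):
            objective_score(q, response(q, ticked=bad))

    def test_other_box_counts_toward_score(self):
        q = eight_code_question()
        r = QuestionResponse(question_id="Q1", other_text="peer support group")
        assert objective_score(q, r) == pytest.approx(1.25)


class TestSubjectiveScore:
    def test_full_activity_not_working_scores_minus_10(self):
        q = eight_code_question()
        r = response(q, 8, LikertRating.NOT_WORKING)
        assert subjective_score(q, r, 10.0) == pytest.approx(-10.0)

    def test_full_activity_very_well_scores_plus_10(self):
        q = eight_code_question()
        r = response(q, 8, LikertRating.WORKING_VERY_WELL)
        assert subjective_score(q, r, 10.0) == pytest.approx(10.0)

    def test_no_activity_scores_0_whatever_the_rating(self):
        q = eight_code_question()
        for likert in LikertRating:
            r = response(q, 0, likert)
            assert subjective_score(q, r, 0.0) == 0.0

    def test_half_activity_working_well_scores_2_5(self):
        q = eight_code_question()
        r = response(q, 4, LikertRating.WORKING_WELL)
        assert subjective_score(q, r, 5.0) == pytest.approx(2.5)

    def test_independent_additive_mode_ignores_objective_level(self):
        q = eight_code_question()
        policy = ScoringPolicy(subjective_mode=SubjectiveMode.INDEPENDENT_ADDITIVE)
        r = response(q, 1, LikertRating.WORKING_WELL)
        assert subjective_score(q, r, 1.25, policy) == pytest.approx(5.0)
        # ...but inactivity still anchors to 0
        r0 = response(q, 0, LikertRating.WORKING_WELL)
        assert subjective_score(q, r0, 0.0, policy) == 0.0


class TestScoreQuestion:
    def test_full_activity_not_working_totals_zero(self):
        q = eight_code_question()
        qs = score_question(q, response(q, 8, LikertRating.NOT_WORKING))
        assert qs.total == pytest.approx(0.0)

    def test_nothing_ticked_totals_zero(self):
        q = eight_code_question()
        assert score_question(q, response(q, 0)).total == 0.0

    def test_question_maximum_is_20(self):
        q = eight_code_question()
        qs = score_question(q, response(q, 8, LikertRating.WORKING_VERY_WELL))
        assert qs.total == pytest.approx(20.0)

    def test_flags_record_markers(self):
        q = eight_code_question()
        qs = score_question(q, response(q, ticked=set(q.none_ids)))
        assert qs.flags.none_selected and not qs.flags.not_relevant_selected


class TestPolicyValidation:
    def test_non_monotone_multipliers_rejected(self):
        bad = {
            LikertRating.WORKING_VERY_WELL: 1.0,
            LikertRating.WORKING_WELL: 0.0,
            LikertRating.REQUIRES_SOME_IMPROVEMENT: 0.5,
            LikertRating.REQUIRES_SIGNIFICANT_IMPROVEMENT: -0.5,
            LikertRating.NOT_WORKING: -1.0,
        }
        with pytest.raises(Exception, match="decreasing"):
            ScoringPolicy(likert_multipliers=bad)

    def test_policy_file_defaults(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"subjective_mode": "independent_additive"}')
        policy = ScoringPolicy.from_file(path)
        assert policy.subjective_mode is SubjectiveMode.INDEPENDENT_ADDITIVE
        assert policy.unanswered_policy is UnansweredPolicy.SCORE_ZERO


class TestScoreOrganisation:
    def _org(self, instr, fill, likert):
        responses = {}
        for q in instr.core_questions:
            ticked = set(q.scoreable_ids) if fill else set()
            responses[q.question_id] = QuestionResponse(
                question_id=q.question_id, ticked_codes=ticked, likert=likert)
        return OrganisationResponse(org_id="A", timepoint="t1",
                                    responses=responses)

    def test_blank_responses_total_zero(self, instrument):
        card = score_organisation(
            instrument, OrganisationResponse(org_id="A", timepoint="t1"))
        assert card.total == 0.0
        assert all(qs.flags.unanswered for qs in card.question_scores.values())

    def test_full_maximum_totals_20(self, instrument):
        card = score_organisation(
            instrument, self._org(instrument, True, LikertRating.WORKING_VERY_WELL))
        assert card.total == pytest.approx(20.0)
        assert card.objective_summary == pytest.approx(10.0)
        assert card.subjective_summary == pytest.approx(10.0)

    def test_wrong_instrument_version_raises(self, instrument):
        org = OrganisationResponse(org_id="A", timepoint="t1", responses={
            "Q99": QuestionResponse(question_id="Q99")})
        with pytest.raises(ScoringError, match="Q99"):
            score_organisation(instrument, org)

    def test_unanswered_policy_changes_denominator(self):
        instr = make_instrument([[4], [4]])
        q1 = instr.get_question("Q1")
        org = OrganisationResponse(org_id="A", timepoint="t1", responses={
            "Q1": QuestionResponse(question_id="Q1",
                                   ticked_codes=set(q1.scoreable_ids),
                                   likert=LikertRating.WORKING_VERY_WELL)})
        card_zero = score_organisation(instr, org)
        card_excl = score_organisation(instr, org, ScoringPolicy(
            unanswered_policy=UnansweredPolicy.EXCLUDE_FROM_DENOMINATOR))
        assert card_zero.total == pytest.approx(10.0)  # (20 + 0) / 2
        assert card_excl.total == pytest.approx(20.0)  # 20 / 1
        assert card_excl.n_scored == 1


class TestOracleEquivalence:
    def test_random_small_instruments_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        for i in range(200):
            instr = random_instrument(rng)
            org = random_response(rng, instr)
            card = score_organisation(instr, org)
            expected = oracle_question_scores(instr.model_dump(mode="json"),
                                              org.model_dump(mode="json"))
            for qid, exp in expected.items():
                got = card.question_scores[qid]
                assert got.objective == pytest.approx(exp["objective"], abs=1e-9)
                assert got.subjective == pytest.approx(exp["subjective"], abs=1e-9)
                assert got.total == pytest.approx(exp["total"], abs=1e-9)

    def test_additive_mode_matches_bruteforce(self):
        rng = np.random.default_rng(99)
        policy = ScoringPolicy(subjective_mode=SubjectiveMode.INDEPENDENT_ADDITIVE)
        for _ in range(100):
            instr = random_instrument(rng)
            org = random_response(rng, instr)
            card = score_organisation(instr, org, policy)
            expected = oracle_question_scores(
                instr.model_dump(mode="json"), org.model_dump(mode="json"),
                mode="independent_additive")
            for qid, exp in expected.items():
                assert card.question_scores[qid].total == pytest.approx(
                    exp["total"], abs=1e-9)


LIKERT_LADDER = [
    LikertRating.NOT_WORKING,
    LikertRating.REQUIRES_SIGNIFICANT_IMPROVEMENT,
    LikertRating.REQUIRES_SOME_IMPROVEMENT,
    LikertRating.WORKING_WELL,
    LikertRating.WORKING_VERY_WELL,
]


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n_codes=st.integers(1, 12), seed=st.integers(0, 10_000))
    def test_adding_a_tick_never_decreases_objective(self, n_codes, seed):
        q = make_question("Q1", [n_codes])
        rng = np.random.default_rng(seed)
        ordered = sorted(q.scoreable_ids)
        k = int(rng.integers(0, n_codes))
        base = objective_score(q, response(q, ticked=set(ordered[:k])))
        more = objective_score(q, response(q, ticked=set(ordered[:k + 1])))
        assert more >= base

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n_codes=st.integers(1, 12), k=st.integers(0, 12),
           step=st.integers(0, 3))
    def test_raising_likert_never_decreases_subjective(self, n_codes, k, step):
        q = make_question("Q1", [n_codes])
        k = min(k, n_codes)
        obj = objective_score(q, response(q, k))
        low = subjective_score(q, response(q, k, LIKERT_LADDER[step]), obj)
        high = subjective_score(q, response(q, k, LIKERT_LADDER[step + 1]), obj)
        assert high >= low

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_scores_respect_printed_bounds(self, seed):
        rng = np.random.default_rng(seed)
        instr = random_instrument(rng)
        org = random_response(rng, instr)
        card = score_organisation(instr, org)
        for qs in card.question_scores.values():
            assert 0.0 <= qs.objective <= 10.0 + 1e-12
            assert -10.0 - 1e-12 <= qs.subjective <= 10.0 + 1e-12
            assert qs.total <= 20.0 + 1e-12
        assert card.total <= 20.0 + 1e-12

    def test_question_order_never_changes_scores(self):
        rng = np.random.default_rng(5)
        instr = random_instrument(rng, max_questions=6)
        org = random_response(rng, instr)
        card = score_organisation(instr, org)
        shuffled = instr.model_copy(update={
            "questions": list(reversed(instr.questions))})
        card2 = score_organisation(shuffled, org)
        assert card2.total == pytest.approx(card.total)
        assert card2.question_scores == card.question_scores
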