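"""The P3C-OCT scoring engine.

Each of the 29 equally weighted core questions is scored out of 20:

* **objective component** (0 to 10): the maximum of 10 points is divided by
  the number of scoreable response codes *n* (activities plus the "Other"
  box), so each ticked code contributes the per-activity weight ``w = 10/n``.
  A question with eight codes therefore awards 1.25 points per tick and 10
  for full activity.  Multi-part questions pool their codes so the maximum
  stays 10.  The "None" and "Not relevant" markers contribute nothing.
* **subjective component** (-10 to +10): the single 5-point Likert rating
  ("working very well" ... "not working") is mapped to a multiplier *m*
  descending from +1 to -1.  Under the default ``scaled_by_objective`` mode
  the subjective score is ``objective x m``: full activity rated "not
  working" scores 10 - 10 = 0 overall, the same as doing nothing at all,
  while full activity rated "working very well" reaches the question maximum
  of 20.  The ratings "not relevant", "none" and "not working" are treated as
  equivalent, as is a blank Likert.

Everything the scheme leaves open (the exact multipliers, whether the
subjective component scales with activity or is an independent +/-10 block,
and how unanswered questions enter the denominator) is surfaced as an
explicit :class:`ScoringPolicy` rather than hard-coded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .instrument import Instrument, Question
from .responses import (
    LIKERT_ORDER,
    LikertRating,
    OrganisationResponse,
    QuestionResponse,
    check_question_response,
)

QUESTION_MAX = 20.0
OBJECTIVE_MAX = 10.0


class ScoringError(ValueError):
    """Raised when a response cannot be scored (conflicting ticks, wrong instrument)."""


class SubjectiveMode(str, Enum):
    SCALED_BY_OBJECTIVE = "scaled_by_objective"
    INDEPENDENT_ADDITIVE = "independent_additive"


class UnansweredPolicy(str, Enum):
    SCORE_ZERO = "score_zero"
    EXCLUDE_FROM_DENOMINATOR = "exclude_from_denominator"


DEFAULT_MULTIPLIERS: dict[LikertRating, float] = {
    LikertRating.WORKING_VERY_WELL: 1.0,
    LikertRating.WORKING_WELL: 0.5,
    LikertRating.REQUIRES_SOME_IMPROVEMENT: 0.0,
    LikertRating.REQUIRES_SIGNIFICANT_IMPROVEMENT: -0.5,
    LikertRating.NOT_WORKING: -1.0,
}


class ScoringPolicy(BaseModel):
    """All scoring knobs in one explicit, serialisable object."""

    model_config = ConfigDict(extra="forbid")

    likert_multipliers: dict[LikertRating, float] = Field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    subjective_mode: SubjectiveMode = SubjectiveMode.SCALED_BY_OBJECTIVE
    unanswered_policy: UnansweredPolicy = UnansweredPolicy.SCORE_ZERO

    @model_validator(mode="after")
    def _check_multipliers(self) -> "ScoringPolicy":
        missing = [r.value for r in LIKERT_ORDER if r not in self.likert_multipliers]
        if missing:
            raise ValueError(f"missing multiplier(s) for: {missing}")
        values = [self.likert_multipliers[r] for r in LIKERT_ORDER]
        if any(a <= b for a, b in zip(values, values[1:])):
            raise ValueError(
                "Likert multipliers must be strictly decreasing from "
                "working_very_well to not_working")
        if values[0] != 1.0 or values[-1] != -1.0:
            raise ValueError("multipliers must span +1 (best) to -1 (worst)")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringPolicy":
        """Load a policy from JSON; omitted fields take their defaults."""
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.model_validate(raw)


@dataclass(frozen=True)
class QuestionFlags:
    unanswered: bool = False
    none_selected: bool = False
    not_relevant_selected: bool = False


@dataclass(frozen=True)
class QuestionScore:
    """Scores for one core question of one organisation."""

    question_id: str
    objective: float
    subjective: float
    total: float
    per_activity_weight: float
    n_scoreable: int
    n_ticked: int
    flags: QuestionFlags = QuestionFlags()


def _effective_multiplier(likert: LikertRating, policy: ScoringPolicy) -> float:
    # blank Likert is treated like "not working" (the none / not relevant /
    # not working equivalence); harmless whenever the objective score is 0
    if likert is LikertRating.UNANSWERED:
        return policy.likert_multipliers[LikertRating.NOT_WORKING]
    try:
        return policy.likert_multipliers[likert]
    except KeyError as exc:  # pragma: no cover - enum already constrains this
        raise ScoringError(f"no multiplier for Likert value {likert!r}") from exc


def _ticked_scoreable(q: Question, r: QuestionResponse) -> set[str]:
    ticked = set(r.ticked_codes)
    if r.other_text and q.other_ids:
        ticked |= q.other_ids
    return ticked & q.scoreable_ids


def objective_score(q: Question, r: QuestionResponse,
                    policy: Optional[ScoringPolicy] = None) -> float:
    """Points in [0, 10]: (number of ticked scoreable codes) x 10/n.

    ``n`` pools the scoreable codes of every objective part of the question,
    so multi-part questions keep an objective maximum of 10.  Conflicting
    ticks (a marker together with an activity) raise :class:`ScoringError`
    rather than being silently scored.
    """
    problems = check_question_response(q, r)
    if problems:
        raise ScoringError(f"{q.question_id}: " + "; ".join(problems))
    n = q.scoreable_count
    if n < 1:
        raise ScoringError(f"{q.question_id}: question has no scoreable codes")
    return len(_ticked_scoreable(q, r)) * (OBJECTIVE_MAX / n)


def subjective_score(q: Question, r: QuestionResponse, objective: float,
                     policy: Optional[ScoringPolicy] = None) -> float:
    """Points in [-10, +10] from the question's Likert rating.

    Default mode scales by the objective score (``objective x m``); the
    ``independent_additive`` mode awards ``10 x m`` regardless of activity,
    forced to 0 when nothing is ticked so that inactivity still scores 0.
    """
    policy = policy or ScoringPolicy()
    m = _effective_multiplier(r.likert, policy)
    if policy.subjective_mode is SubjectiveMode.SCALED_BY_OBJECTIVE:
        return objective * m
    if not _ticked_scoreable(q, r):
        return 0.0
    return OBJECTIVE_MAX * m


def score_question(q: Question, r: QuestionResponse,
                   policy: Optional[ScoringPolicy] = None) -> QuestionScore:
    """Objective + subjective scores and flags for one answered question."""
    policy = policy or ScoringPolicy()
    obj = objective_score(q, r, policy)
    subj = subjective_score(q, r, obj, policy)
    ticked = set(r.ticked_codes)
    if r.other_text and q.other_ids:
        ticked |= q.other_ids
    return QuestionScore(
        question_id=q.question_id,
        objective=obj,
        subjective=subj,
        total=obj + subj,
        per_activity_weight=OBJECTIVE_MAX / q.scoreable_count,
        n_scoreable=q.scoreable_count,
        n_ticked=len(ticked & q.scoreable_ids),
        flags=QuestionFlags(
            unanswered=False,
            none_selected=bool(ticked & q.none_ids),
            not_relevant_selected=bool(ticked & q.not_relevant_ids),
        ),
    )


def unanswered_score(q: Question) -> QuestionScore:
    """The zero score recorded for a core question with no response at all."""
    return QuestionScore(
        question_id=q.question_id, objective=0.0, subjective=0.0, total=0.0,
        per_activity_weight=OBJECTIVE_MAX / q.scoreable_count,
        n_scoreable=q.scoreable_count, n_ticked=0,
        flags=QuestionFlags(unanswered=True),
    )


def score_organisation(instr: Instrument, resp: OrganisationResponse,
                       policy: Optional[ScoringPolicy] = None):
    """Score every core question of one organisation and aggregate to a ScoreCard.

    Reflective and demographic questions are never scored.  Responses that
    reference question ids absent from ``instr`` (a different instrument
    version) raise :class:`ScoringError`.
    """
    from .aggregation import aggregate  # local import to avoid a cycle

    policy = policy or ScoringPolicy()
    unknown = sorted(set(resp.responses) - set(instr.question_map))
    if unknown:
        raise ScoringError(
            f"org {resp.org_id!r} references question ids not in instrument "
            f"{instr.name} v{instr.version}: {', '.join(unknown)}")
    scores: dict[str, QuestionScore] = {}
    for q in instr.core_questions:
        r = resp.responses.get(q.question_id)
        if r is None:
            scores[q.question_id] = unanswered_score(q)
        else:
            scores[q.question_id] = score_question(q, r, policy)
    return aggregate(scores, instr, org_id=resp.org_id, timepoint=resp.timepoint,
                     policy=policy)
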