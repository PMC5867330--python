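"""Shared test utilities: tiny instrument factories, random generators and a
naive brute-force scoring oracle kept deliberately independent of the engine
(it works on plain dicts and recounts everything with explicit loops)."""

from __future__ import annotations

import numpy as np

from p3c_oct.instrument import (
    CodeCategory,
    Instrument,
    ObjectivePart,
    Question,
    QuestionRole,
    ResponseCode,
    OperationalLevel,
)
from p3c_oct.responses import LikertRating, OrganisationResponse, QuestionResponse

LIKERT_TOKENS = [r.value for r in LikertRating]


def make_part(qid: str, part_no: int, n_activities: int, with_other: bool = True,
              with_not_relevant: bool = True) -> ObjectivePart:
    codes = [
        ResponseCode(code_id=f"{qid}.p{part_no}.a{i}", label=f"activity {i}",
                     category=CodeCategory.ACTIVITY)
        for i in range(n_activities)
    ]
    if with_other:
        codes.append(ResponseCode(code_id=f"{qid}.p{part_no}.other", label="Other",
                                  category=CodeCategory.OTHER))
    codes.append(ResponseCode(code_id=f"{qid}.p{part_no}.none", label="None",
                              category=CodeCategory.NONE_MARKER))
    if with_not_relevant:
        codes.append(ResponseCode(code_id=f"{qid}.p{part_no}.nr", label="Not relevant",
                                  category=CodeCategory.NOT_RELEVANT_MARKER))
    return ObjectivePart(part_id=f"{qid}.p{part_no}", codes=codes)


def make_question(qid: str, scoreable_per_part: list[int],
                  domain: str = "d1", subdomains=("s1",),
                  level=OperationalLevel.PERSON_PRACTITIONER) -> Question:
    parts = []
    for i, n in enumerate(scoreable_per_part, start=1):
        with_other = n > 1  # single-code parts are a lone activity
        parts.append(make_part(qid, i, n - 1 if with_other else n,
                               with_other=with_other))
    return Question(question_id=qid, text=f"question {qid}", role=QuestionRole.CORE,
                    operational_level=level, domain=domain,
                    subdomains=list(subdomains), parts=parts, has_likert=True)


def make_instrument(scoreable_counts: list[list[int]],
                    name: str = "tiny") -> Instrument:
    questions = [make_question(f"Q{i+1}", sizes)
                 for i, sizes in enumerate(scoreable_counts)]
    return Instrument(name=name, version="0",
                      questions=questions,
                      domain_catalogue={"d1": ["s1"]})


def random_instrument(rng: np.random.Generator, max_questions: int = 10) -> Instrument:
    n_q = int(rng.integers(1, max_questions + 1))
    sizes = []
    for _ in range(n_q):
        n_parts = int(rng.integers(1, 3))
        sizes.append([int(rng.integers(1, 9)) for _ in range(n_parts)])
    return make_instrument(sizes)


def random_response(rng: np.random.Generator, instr: Instrument,
                    org_id: str = "org", timepoint: str = "t1",
                    p_answer: float = 0.9) -> OrganisationResponse:
    responses = {}
    for q in instr.core_questions:
        if rng.random() > p_answer:
            continue  # unanswered question
        ticked = set()
        for part in q.parts:
            part_ticks = {c.code_id for c in part.scoreable_codes
                          if rng.random() < 0.5}
            if part_ticks:
                ticked |= part_ticks
            elif rng.random() < 0.5:
                ticked |= {c.code_id for c in part.codes
                           if c.category is CodeCategory.NONE_MARKER}
        likert = LikertRating(LIKERT_TOKENS[int(rng.integers(0, 6))])
        responses[q.question_id] = QuestionResponse(
            question_id=q.question_id, ticked_codes=ticked, likert=likert)
    return OrganisationResponse(org_id=org_id, timepoint=timepoint,
                                responses=responses)


# ---------------------------------------------------------------------------
# the brute-force oracle: plain dicts, explicit loops, no engine imports

ORACLE_MULTIPLIERS = {
    "working_very_well": 1.0,
    "working_well": 0.5,
    "requires_some_improvement": 0.0,
    "requires_significant_improvement": -0.5,
    "not_working": -1.0,
    "unanswered": -1.0,  # blank rating falls back to the not-working equivalence
}


def oracle_question_scores(instr_dict: dict, resp_dict: dict,
                           mode: str = "scaled_by_objective") -> dict[str, dict]:
    """Recompute every core question's scores from raw dict structures."""
    out = {}
    for q in instr_dict["questions"]:
        if q["role"] != "core":
            continue
        scoreable = []
        other_ids = []
        for part in q["parts"]:
            for code in part["codes"]:
                if code["category"] in ("activity", "other"):
                    scoreable.append(code["code_id"])
                if code["category"] == "other":
                    other_ids.append(code["code_id"])
        n = len(scoreable)
        r = resp_dict["responses"].get(q["question_id"])
        if r is None:
            out[q["question_id"]] = {"objective": 0.0, "subjective": 0.0,
                                     "total": 0.0, "unanswered": True}
            continue
        ticked = set(r.get("ticked_codes", []))
        if r.get("other_text"):
            ticked |= set(other_ids)
        k = 0
        for cid in scoreable:
            if cid in ticked:
                k += 1
        obj = k * 10.0 / n
        m = ORACLE_MULTIPLIERS[r.get("likert", "unanswered")]
        if mode == "scaled_by_objective":
            subj = obj * m
        else:
            subj = 0.0 if k == 0 else 10.0 * m
        out[q["question_id"]] = {"objective": obj, "subjective": subj,
                                 "total": obj + subj, "unanswered": False}
    return out


def oracle_total(instr_dict: dict, resp_dict: dict,
                 mode: str = "scaled_by_objective") -> float:
    scores = oracle_question_scores(instr_dict, resp_dict, mode)
    totals = [s["total"] for s in scores.values()]
    return sum(totals) / len(totals) if totals else 0.0
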