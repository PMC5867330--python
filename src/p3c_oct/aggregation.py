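"""Aggregation of question scores to organisation-level summaries and benchmarks.

The instrument total is normalised to the 20-point question scale by taking
the mean of the (equally weighted) question totals; summing and rescaling by
``20 / (20 N)`` is algebraically identical.  Objective and subjective
summaries are the corresponding means on their own scales (max 10 and
+/-10).  Domain scores average over each domain's member questions using
primary-domain membership, so a question tapping several subdomains is never
double-counted inside its own domain; operational-level scores average over
level listings (a question listed under two levels contributes to both
means).  Overlapping subdomain views are available separately via
:func:`subdomain_scores`.

Benchmarking compares one organisation against either the cohort aggregate
(delta = organisation minus cohort mean, so deltas sum to zero across the
cohort) or the organisation's own score at an earlier timepoint (an internal
benchmark).  Percentile ranks use the mid-rank convention
``100 x (#below + 0.5 #equal) / cohort size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .instrument import Instrument, OperationalLevel
from .scoring import (
    QuestionFlags,
    QuestionScore,
    ScoringPolicy,
    UnansweredPolicy,
)


@dataclass
class ScoreCard:
    """All scores for one organisation at one timepoint."""

    org_id: str
    timepoint: str
    question_scores: dict[str, QuestionScore]
    total: float
    objective_summary: float
    subjective_summary: float
    domain_scores: dict[str, float]
    level_scores: dict[str, float]
    n_scored: int


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else 0.0


def aggregate(question_scores: Union[Mapping[str, QuestionScore],
                                     Iterable[QuestionScore]],
              instr: Instrument,
              org_id: str = "",
              timepoint: str = "",
              policy: Optional[ScoringPolicy] = None) -> ScoreCard:
    """Build a :class:`ScoreCard` from per-question scores.

    Under the default ``score_zero`` unanswered policy all core questions
    enter every mean; under ``exclude_from_denominator`` questions flagged
    unanswered are dropped from the denominators instead of scoring 0.
    """
    policy = policy or ScoringPolicy()
    if not isinstance(question_scores, Mapping):
        question_scores = {qs.question_id: qs for qs in question_scores}
    core_ids = {q.question_id for q in instr.core_questions}
    unknown = sorted(set(question_scores) - core_ids)
    if unknown:
        raise ValueError(f"scores given for unknown/non-core question(s): {unknown}")

    exclude = policy.unanswered_policy is UnansweredPolicy.EXCLUDE_FROM_DENOMINATOR
    included = {qid: qs for qid, qs in question_scores.items()
                if not (exclude and qs.flags.unanswered)}

    totals = [qs.total for qs in included.values()]
    domain_scores = {}
    for domain in instr.domain_catalogue:
        members = [question_scores[q.question_id].total
                   for q in instr.core_questions
                   if q.domain == domain and q.question_id in included]
        if members:
            domain_scores[domain] = _mean(members)
    level_scores = {}
    for level in OperationalLevel:
        members = [question_scores[q.question_id].total
                   for q in instr.level_members(level)
                   if q.question_id in included]
        if members:
            level_scores[level.value] = _mean(members)

    return ScoreCard(
        org_id=org_id,
        timepoint=timepoint,
        question_scores=dict(question_scores),
        total=_mean(totals),
        objective_summary=_mean([qs.objective for qs in included.values()]),
        subjective_summary=_mean([qs.subjective for qs in included.values()]),
        domain_scores=domain_scores,
        level_scores=level_scores,
        n_scored=len(included),
    )


def subdomain_scores(card: ScoreCard, instr: Instrument) -> dict[str, float]:
    """Mean question total per subdomain; subdomain views overlap by design."""
    out = {}
    for subs in instr.domain_catalogue.values():
        for s in subs:
            members = [card.question_scores[q.question_id].total
                       for q in instr.core_questions
                       if s in q.subdomains and q.question_id in card.question_scores]
            if members:
                out[s] = _mean(members)
    return out


def percentile_rank(values: list[float], x: float) -> float:
    """Mid-rank percentile of ``x`` within ``values`` (ties share the mean rank)."""
    if not values:
        raise ValueError("empty cohort")
    below = sum(v < x for v in values)
    equal = sum(v == x for v in values)
    return 100.0 * (below + 0.5 * equal) / len(values)


@dataclass
class BenchmarkView:
    """One organisation compared against a reference at every granularity."""

    org_id: str
    timepoint: str
    reference: str  # "cohort" or a prior timepoint label
    total_delta: float
    domain_deltas: dict[str, float] = field(default_factory=dict)
    question_deltas: dict[str, float] = field(default_factory=dict)
    percentile_total: float = 50.0
    percentile_domains: dict[str, float] = field(default_factory=dict)
    n_reference: int = 0


def benchmark(cards: list[ScoreCard], subject: str,
              reference: str = "cohort") -> BenchmarkView:
    """Benchmark ``subject`` against the cohort mean or a prior timepoint.

    With ``reference="cohort"`` every card in ``cards`` (including the
    subject's) forms the comparison cohort, which must hold exactly one card
    per organisation.  With a timepoint label, the subject's card at that
    timepoint is the internal reference for its card at the other timepoint;
    percentiles are then computed within the cards sharing the subject's
    current timepoint.
    """
    if not cards:
        raise ValueError("empty cohort")
    subject_cards = [c for c in cards if c.org_id == subject]
    if not subject_cards:
        raise ValueError(f"subject {subject!r} absent from cohort")

    if reference == "cohort":
        orgs = [c.org_id for c in cards]
        if len(orgs) != len(set(orgs)):
            raise ValueError(
                "cohort benchmarking needs one card per organisation; "
                "filter to a single timepoint first")
        card = subject_cards[0]
        ref_cards = cards
        ref_total = _mean([c.total for c in ref_cards])
        domain_ref = {d: _mean([c.domain_scores[d] for c in ref_cards
                                if d in c.domain_scores])
                      for d in card.domain_scores}
        question_ref = {qid: _mean([c.question_scores[qid].total for c in ref_cards
                                    if qid in c.question_scores])
                        for qid in card.question_scores}
        label = "cohort"
    else:
        prior = [c for c in subject_cards if c.timepoint == reference]
        current = [c for c in subject_cards if c.timepoint != reference]
        if not prior:
            raise ValueError(
                f"subject {subject!r} has no card at reference timepoint {reference!r}")
        if len(current) != 1:
            raise ValueError(
                f"subject {subject!r} needs exactly one card outside the reference "
                f"timepoint, found {len(current)}")
        ref, card = prior[0], current[0]
        ref_cards = [c for c in cards if c.timepoint == card.timepoint]
        ref_total = ref.total
        domain_ref = {d: ref.domain_scores.get(d, 0.0) for d in card.domain_scores}
        question_ref = {qid: ref.question_scores[qid].total
                        for qid in card.question_scores
                        if qid in ref.question_scores}
        label = reference

    cohort_totals = [c.total for c in ref_cards]
    percentile_domains = {}
    for d in card.domain_scores:
        pool = [c.domain_scores[d] for c in ref_cards if d in c.domain_scores]
        if pool:
            percentile_domains[d] = percentile_rank(pool, card.domain_scores[d])
    return BenchmarkView(
        org_id=subject,
        timepoint=card.timepoint,
        reference=label,
        total_delta=card.total - ref_total,
        domain_deltas={d: card.domain_scores[d] - domain_ref[d]
                       for d in card.domain_scores},
        question_deltas={qid: card.question_scores[qid].total - question_ref[qid]
                         for qid in question_ref},
        percentile_total=percentile_rank(cohort_totals, card.total),
        percentile_domains=percentile_domains,
        n_reference=len(ref_cards),
    )


# ---------------------------------------------------------------------------
# plain-dict (de)serialisation used by the CLI and dashboard

def card_to_dict(card: ScoreCard) -> dict:
    return {
        "org_id": card.org_id,
        "timepoint": card.timepoint,
        "total": card.total,
        "objective_summary": card.objective_summary,
        "subjective_summary": card.subjective_summary,
        "domain_scores": dict(card.domain_scores),
        "level_scores": dict(card.level_scores),
        "n_scored": card.n_scored,
        "question_scores": {
            qid: {
                "objective": qs.objective,
                "subjective": qs.subjective,
                "total": qs.total,
                "per_activity_weight": qs.per_activity_weight,
                "n_scoreable": qs.n_scoreable,
                "n_ticked": qs.n_ticked,
                "flags": {
                    "unanswered": qs.flags.unanswered,
                    "none_selected": qs.flags.none_selected,
                    "not_relevant_selected": qs.flags.not_relevant_selected,
                },
            }
            for qid, qs in sorted(card.question_scores.items())
        },
    }


def card_from_dict(d: dict) -> ScoreCard:
    question_scores = {
        qid: QuestionScore(
            question_id=qid,
            objective=qs["objective"],
            subjective=qs["subjective"],
            total=qs["total"],
            per_activity_weight=qs["per_activity_weight"],
            n_scoreable=qs["n_scoreable"],
            n_ticked=qs["n_ticked"],
            flags=QuestionFlags(**qs["flags"]),
        )
        for qid, qs in d["question_scores"].items()
    }
    return ScoreCard(
        org_id=d["org_id"],
        timepoint=d["timepoint"],
        question_scores=question_scores,
        total=d["total"],
        objective_summary=d["objective_summary"],
        subjective_summary=d["subjective_summary"],
        domain_scores=dict(d["domain_scores"]),
        level_scores=dict(d["level_scores"]),
        n_scored=d["n_scored"],
    )
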