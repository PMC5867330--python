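"""Reading, validating and writing completed P3C-OCT responses.

One :class:`OrganisationResponse` holds everything a single organisation
submitted at a single timepoint: the ticked response codes and Likert rating
per question, free-text comments, and organisational demographics.

Two file surfaces are supported:

* a flat CSV with header
  ``org_id,timepoint,question_id,ticked_codes,other_text,likert,comment``
  (``ticked_codes`` is a semicolon-joined list) — the format a practice
  manager can produce from a spreadsheet.  Demographics are not representable
  in the flat CSV;
* a JSON mirror of :class:`OrganisationResponse`, which carries demographics
  and the optional ISO date of completion.

A question absent from a file is *unanswered*, which is distinct from ticking
the "None" marker; how unanswered questions score is a policy knob of the
scoring engine, not of this module.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .instrument import Instrument, Question


class LikertRating(str, Enum):
    """The 5-point rating of how well a question's activities are working."""

    WORKING_VERY_WELL = "working_very_well"
    WORKING_WELL = "working_well"
    REQUIRES_SOME_IMPROVEMENT = "requires_some_improvement"
    REQUIRES_SIGNIFICANT_IMPROVEMENT = "requires_significant_improvement"
    NOT_WORKING = "not_working"
    UNANSWERED = "unanswered"


#: the five substantive ratings, best first
LIKERT_ORDER: list[LikertRating] = [
    LikertRating.WORKING_VERY_WELL,
    LikertRating.WORKING_WELL,
    LikertRating.REQUIRES_SOME_IMPROVEMENT,
    LikertRating.REQUIRES_SIGNIFICANT_IMPROVEMENT,
    LikertRating.NOT_WORKING,
]


class QuestionResponse(BaseModel):
    model_config = ConfigDict(extra="forbid")

    question_id: str
    ticked_codes: set[str] = Field(default_factory=set)
    other_text: Optional[str] = None
    likert: LikertRating = LikertRating.UNANSWERED
    comment: Optional[str] = None


class OrganisationResponse(BaseModel):
    model_config = ConfigDict(extra="forbid")

    org_id: str
    timepoint: str
    date: Optional[str] = None
    responses: dict[str, QuestionResponse] = Field(default_factory=dict)
    demographics: dict[str, str] = Field(default_factory=dict)


@dataclass(frozen=True)
class Issue:
    org_id: str
    timepoint: str
    question_id: Optional[str]
    kind: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def of_kind(self, kind: str) -> list[Issue]:
        return [i for i in self.issues if i.kind == kind]

    def __str__(self) -> str:
        if self.ok:
            return "no issues"
        return "\n".join(
            f"[{i.kind}] org={i.org_id} t={i.timepoint}"
            + (f" q={i.question_id}" if i.question_id else "")
            + f": {i.message}"
            for i in self.issues
        )


class ResponseValidationError(ValueError):
    """Raised on structurally invalid response files; carries every issue found."""

    def __init__(self, report: ValidationReport):
        super().__init__(f"{len(report.issues)} response validation issue(s):\n{report}")
        self.report = report


def _nat_key(code_id: str) -> tuple:
    """Sort Q2 before Q10 and Q1.a before Q1.b."""
    out: list = []
    num = ""
    for ch in code_id:
        if ch.isdigit():
            num += ch
        else:
            if num:
                out.append((1, int(num)))
                num = ""
            out.append((0, ch))
    if num:
        out.append((1, int(num)))
    return tuple(out)


_LIKERT_ALIASES = {r.value: r for r in LikertRating}
_LIKERT_ALIASES.update({r.value.replace("_", " "): r for r in LikertRating})
_LIKERT_ALIASES[""] = LikertRating.UNANSWERED


def parse_likert(token: str) -> LikertRating:
    key = (token or "").strip().lower().replace("-", " ")
    key2 = key.replace(" ", "_")
    if key in _LIKERT_ALIASES:
        return _LIKERT_ALIASES[key]
    if key2 in {r.value for r in LikertRating}:
        return LikertRating(key2)
    raise ValueError(f"unknown Likert token {token!r}")


def check_question_response(q: Question, r: QuestionResponse) -> list[str]:
    """Structural problems of one response against its question definition."""
    problems = []
    unknown = sorted(r.ticked_codes - q.all_code_ids, key=_nat_key)
    if unknown:
        problems.append(f"unknown code id(s): {', '.join(unknown)}")
    # markers conflict with activity ticks within the same objective part;
    # a multi-part question may mix activity in one part with "None" in another
    for part in q.parts:
        marker_ids = {c.code_id for c in part.codes
                      if c.category.value in ("none_marker", "not_relevant_marker")}
        scoreable_ids = {c.code_id for c in part.scoreable_codes}
        markers = marker_ids & r.ticked_codes
        activities = scoreable_ids & r.ticked_codes
        if markers and activities:
            problems.append(
                "conflicting ticks: 'none'/'not relevant' markers are equivalent "
                f"to no activity and cannot be combined with activity codes in "
                f"the same part (markers {sorted(markers, key=_nat_key)}, "
                f"activities {sorted(activities, key=_nat_key)})"
            )
    return problems


def _normalise(org: OrganisationResponse, instr: Instrument,
               issues: list[Issue]) -> None:
    """Apply the other-text rule and collect structural issues (in place)."""
    qmap = instr.question_map
    for qid, qr in org.responses.items():
        if qid not in qmap:
            issues.append(Issue(org.org_id, org.timepoint, qid, "unknown_question",
                                f"question id {qid!r} not in instrument"))
            continue
        q = qmap[qid]
        # a filled "other" box implies the other code is ticked
        if qr.other_text and q.other_ids:
            qr.ticked_codes |= q.other_ids
        for msg in check_question_response(q, qr):
            kind = "conflict" if msg.startswith("conflicting") else "unknown_code"
            issues.append(Issue(org.org_id, org.timepoint, qid, kind, msg))


def read_responses(path: str | Path, instr: Instrument) -> list[OrganisationResponse]:
    """Read a CSV or JSON response file, validated against ``instr``.

    Returns organisations sorted by ``(org_id, timepoint)``.  Unknown
    question/code ids and conflicting ticks raise
    :class:`ResponseValidationError` listing every problem found.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        cohort = _read_json(path)
    else:
        cohort = _read_csv(path)
    issues: list[Issue] = []
    for org in cohort:
        _normalise(org, instr, issues)
    if issues:
        raise ResponseValidationError(ValidationReport(issues))
    cohort.sort(key=lambda o: (o.org_id, o.timepoint))
    return cohort


def _read_csv(path: Path) -> list[OrganisationResponse]:
    orgs: dict[tuple[str, str], OrganisationResponse] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = {"org_id", "timepoint", "question_id", "ticked_codes",
                    "other_text", "likert", "comment"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            missing = sorted(expected - set(reader.fieldnames or []))
            raise ResponseValidationError(ValidationReport([Issue(
                "", "", None, "format",
                f"{path}: CSV header missing column(s): {', '.join(missing)}")]))
        for row in reader:
            key = (row["org_id"], row["timepoint"])
            org = orgs.setdefault(key, OrganisationResponse(
                org_id=row["org_id"], timepoint=row["timepoint"]))
            ticked = {c.strip() for c in (row["ticked_codes"] or "").split(";")
                      if c.strip()}
            org.responses[row["question_id"]] = QuestionResponse(
                question_id=row["question_id"],
                ticked_codes=ticked,
                other_text=row["other_text"] or None,
                likert=parse_likert(row["likert"]),
                comment=row["comment"] or None,
            )
    return list(orgs.values())


def _read_json(path: Path) -> list[OrganisationResponse]:
    raw = json.loads(path.read_text(encoding="utf-8"))
    if isinstance(raw, dict):
        raw = raw.get("organisations", [])
    return [OrganisationResponse.model_validate(entry) for entry in raw]


def write_responses(cohort: list[OrganisationResponse], path: str | Path) -> Path:
    """Write a cohort to CSV or JSON (chosen by file suffix), deterministically."""
    path = Path(path)
    ordered = sorted(cohort, key=lambda o: (o.org_id, o.timepoint))
    if path.suffix.lower() == ".json":
        payload = {"organisations": []}
        for org in ordered:
            d = org.model_dump(mode="json")
            d["responses"] = {
                qid: {**qr, "ticked_codes": sorted(qr["ticked_codes"], key=_nat_key)}
                for qid, qr in sorted(d["responses"].items(),
                                      key=lambda kv: _nat_key(kv[0]))
            }
            payload["organisations"].append(d)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   ensure_ascii=False) + "\n", encoding="utf-8")
        return path
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["org_id", "timepoint", "question_id", "ticked_codes",
                         "other_text", "likert", "comment"])
        for org in ordered:
            for qid in sorted(org.responses, key=_nat_key):
                qr = org.responses[qid]
                writer.writerow([
                    org.org_id, org.timepoint, qid,
                    ";".join(sorted(qr.ticked_codes, key=_nat_key)),
                    qr.other_text or "",
                    "" if qr.likert is LikertRating.UNANSWERED else qr.likert.value,
                    qr.comment or "",
                ])
    return path


def validate_responses(cohort: list[OrganisationResponse],
                       instr: Instrument) -> ValidationReport:
    """Report (never raise, never mutate) quality issues across a cohort.

    Issues reported: duplicate ``(org, timepoint)`` pairs, unknown question or
    code ids, conflicting ticks, missing core questions, and answered core
    questions with an unanswered Likert.
    """
    issues: list[Issue] = []
    seen: set[tuple[str, str]] = set()
    core_ids = [q.question_id for q in instr.core_questions]
    qmap = instr.question_map
    for org in cohort:
        key = (org.org_id, org.timepoint)
        if key in seen:
            issues.append(Issue(org.org_id, org.timepoint, None, "duplicate",
                                "duplicate (org_id, timepoint) in cohort"))
        seen.add(key)
        for qid in core_ids:
            if qid not in org.responses:
                issues.append(Issue(org.org_id, org.timepoint, qid, "missing",
                                    "core question not answered"))
        for qid, qr in org.responses.items():
            if qid not in qmap:
                issues.append(Issue(org.org_id, org.timepoint, qid,
                                    "unknown_question",
                                    f"question id {qid!r} not in instrument"))
                continue
            q = qmap[qid]
            for msg in check_question_response(q, qr):
                kind = "conflict" if msg.startswith("conflicting") else "unknown_code"
                issues.append(Issue(org.org_id, org.timepoint, qid, kind, msg))
            if q.has_likert and qr.likert is LikertRating.UNANSWERED:
                issues.append(Issue(org.org_id, org.timepoint, qid,
                                    "unanswered_likert",
                                    "Likert rating left blank"))
    return ValidationReport(issues)
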