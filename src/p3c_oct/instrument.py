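"""Machine-readable definition of the P3C Organisational Change Tool (P3C-OCT).

The P3C-OCT is a self-assessment instrument for health and care organisations
(typically UK general practices) that measures activity towards Person-Centred
Coordinated Care (P3C).  It consists of 29 equally weighted core questions
spread over four operational levels (person-practitioner interaction,
practitioner-practitioner interaction, organisational systems and support,
information systems/IT), two reflective free-text questions and a small block
of organisational demographics.  Each core question carries a checklist of
*response codes* — concrete activities an organisation may perform — plus an
"Other (please specify)" box and the non-scoring markers "None" and
"Not relevant", and a single 5-point Likert rating of how well the listed
activities are working.

This module defines the schema for the instrument, a loader/validator with a
canonical (sorted-key JSON) serialisation, per-domain and per-level summary
tables, and the bundled default instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class OperationalLevel(str, Enum):
    """Where a core question's activities predominantly operate."""

    PERSON_PRACTITIONER = "person_practitioner"
    PRACTITIONER_PRACTITIONER = "practitioner_practitioner"
    ORGANISATIONAL_SYSTEMS = "organisational_systems"
    INFORMATION_SYSTEMS = "information_systems"


class QuestionRole(str, Enum):
    CORE = "core"
    REFLECTIVE_TEXTBOX = "reflective_textbox"
    DEMOGRAPHIC = "demographic"


class CodeCategory(str, Enum):
    """Kind of response code inside a question's checklist.

    ``activity`` and ``other`` are scoreable; ``none_marker`` and
    ``not_relevant_marker`` explicitly record the absence/irrelevance of
    activity and never contribute points.
    """

    ACTIVITY = "activity"
    OTHER = "other"
    NONE_MARKER = "none_marker"
    NOT_RELEVANT_MARKER = "not_relevant_marker"


SCOREABLE_CATEGORIES = frozenset({CodeCategory.ACTIVITY, CodeCategory.OTHER})


class InstrumentError(ValueError):
    """Raised when an instrument file fails to parse or validate.

    ``issues`` holds one human-readable entry per violation so callers see
    every problem, not just the first.
    """

    def __init__(self, message: str, issues: Optional[list[str]] = None):
        super().__init__(message)
        self.issues: list[str] = issues if issues is not None else [message]


class ResponseCode(BaseModel):
    """A single selectable entry in a question's checklist."""

    model_config = ConfigDict(extra="forbid")

    code_id: str
    label: str
    category: CodeCategory = CodeCategory.ACTIVITY
    placeholder: bool = False


class ObjectivePart(BaseModel):
    """One objective checklist of a question.

    Most questions have a single part; a question may carry several parts
    whose scoreable codes are pooled at scoring time so the question's
    objective maximum stays 10.
    """

    model_config = ConfigDict(extra="forbid")

    part_id: str
    prompt: str = ""
    codes: list[ResponseCode]

    @model_validator(mode="after")
    def _check_part(self) -> "ObjectivePart":
        issues = []
        ids = [c.code_id for c in self.codes]
        if len(ids) != len(set(ids)):
            issues.append(f"part {self.part_id}: duplicate code_id")
        n_none = sum(c.category is CodeCategory.NONE_MARKER for c in self.codes)
        n_nr = sum(c.category is CodeCategory.NOT_RELEVANT_MARKER for c in self.codes)
        n_other = sum(c.category is CodeCategory.OTHER for c in self.codes)
        if n_none != 1:
            issues.append(f"part {self.part_id}: expected exactly one none_marker, found {n_none}")
        if n_nr > 1:
            issues.append(f"part {self.part_id}: at most one not_relevant_marker allowed, found {n_nr}")
        if n_other > 1:
            issues.append(f"part {self.part_id}: at most one 'other' code allowed, found {n_other}")
        if self.scoreable_count < 1:
            issues.append(f"part {self.part_id}: needs at least one scoreable code")
        if issues:
            raise ValueError("; ".join(issues))
        return self

    @property
    def scoreable_codes(self) -> list[ResponseCode]:
        return [c for c in self.codes if c.category in SCOREABLE_CATEGORIES]

    @property
    def scoreable_count(self) -> int:
        return len(self.scoreable_codes)


class Question(BaseModel):
    model_config = ConfigDict(extra="forbid")

    question_id: str
    text: str
    role: QuestionRole = QuestionRole.CORE
    operational_level: Optional[OperationalLevel] = None
    secondary_levels: list[OperationalLevel] = Field(default_factory=list)
    domain: Optional[str] = None
    subdomains: list[str] = Field(default_factory=list)
    parts: list[ObjectivePart] = Field(default_factory=list)
    has_likert: bool = False
    tags: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_question(self) -> "Question":
        issues = []
        if self.role is QuestionRole.CORE:
            if not self.parts:
                issues.append(f"{self.question_id}: core question needs >=1 objective part")
            if not self.has_likert:
                issues.append(f"{self.question_id}: core question must carry a Likert rating")
            if self.operational_level is None:
                issues.append(f"{self.question_id}: core question needs an operational_level")
            if self.domain is None:
                issues.append(f"{self.question_id}: core question needs a primary domain")
        else:
            if self.parts:
                issues.append(f"{self.question_id}: non-core question may not have objective parts")
            if self.has_likert:
                issues.append(f"{self.question_id}: non-core question may not have a Likert rating")
        if self.operational_level is not None and self.operational_level in self.secondary_levels:
            issues.append(f"{self.question_id}: primary level repeated in secondary_levels")
        if issues:
            raise ValueError("; ".join(issues))
        return self

    # -- scoring helpers (codes are pooled across parts) -----------------
    @property
    def scoreable_count(self) -> int:
        """Pooled number of scoreable codes, the n in the per-activity weight 10/n."""
        return sum(p.scoreable_count for p in self.parts)

    @property
    def scoreable_ids(self) -> set[str]:
        return {c.code_id for p in self.parts for c in p.codes if c.category in SCOREABLE_CATEGORIES}

    @property
    def other_ids(self) -> set[str]:
        return {c.code_id for p in self.parts for c in p.codes if c.category is CodeCategory.OTHER}

    @property
    def none_ids(self) -> set[str]:
        return {c.code_id for p in self.parts for c in p.codes if c.category is CodeCategory.NONE_MARKER}

    @property
    def not_relevant_ids(self) -> set[str]:
        return {c.code_id for p in self.parts for c in p.codes
                if c.category is CodeCategory.NOT_RELEVANT_MARKER}

    @property
    def all_code_ids(self) -> set[str]:
        return {c.code_id for p in self.parts for c in p.codes}

    @property
    def levels(self) -> list[OperationalLevel]:
        """All operational levels the question is listed under."""
        out = []
        if self.operational_level is not None:
            out.append(self.operational_level)
        out.extend(self.secondary_levels)
        return out


class Instrument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    version: str
    questions: list[Question]
    domain_catalogue: dict[str, list[str]] = Field(default_factory=dict)
    notes: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_instrument(self) -> "Instrument":
        issues = []
        qids = [q.question_id for q in self.questions]
        if len(qids) != len(set(qids)):
            seen, dups = set(), set()
            for qid in qids:
                (dups if qid in seen else seen).add(qid)
            issues.append(f"duplicate question ids: {sorted(dups)}")
        sub_to_dom = {}
        for dom, subs in self.domain_catalogue.items():
            for s in subs:
                if s in sub_to_dom:
                    issues.append(f"subdomain {s!r} listed under both {sub_to_dom[s]!r} and {dom!r}")
                sub_to_dom[s] = dom
        for q in self.questions:
            if q.domain is not None and q.domain not in self.domain_catalogue:
                issues.append(f"{q.question_id}: unknown domain {q.domain!r}")
            for s in q.subdomains:
                if s not in sub_to_dom:
                    issues.append(f"{q.question_id}: unknown subdomain {s!r}")
            ids = [c.code_id for p in q.parts for c in p.codes]
            if len(ids) != len(set(ids)):
                issues.append(f"{q.question_id}: code ids not unique across parts")
        if issues:
            raise ValueError("; ".join(issues))
        return self

    @property
    def core_questions(self) -> list[Question]:
        return [q for q in self.questions if q.role is QuestionRole.CORE]

    @property
    def n_core_questions(self) -> int:
        return len(self.core_questions)

    @property
    def n_scoreable_codes(self) -> int:
        """Total scoreable response codes (activities + 'other') across core questions."""
        return sum(q.scoreable_count for q in self.core_questions)

    def get_question(self, question_id: str) -> Question:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)

    @property
    def question_map(self) -> dict[str, Question]:
        return {q.question_id: q for q in self.questions}

    @property
    def subdomain_to_domain(self) -> dict[str, str]:
        return {s: d for d, subs in self.domain_catalogue.items() for s in subs}

    def domain_members(self, domain: str) -> list[Question]:
        """Core questions counted as items of ``domain``.

        A question belongs to a domain if the domain is its primary domain or
        if it taps any of the domain's subdomains; cross-domain subdomain tags
        are how one question can appear as an item of more than one domain.
        """
        subs = set(self.domain_catalogue.get(domain, []))
        return [q for q in self.core_questions
                if q.domain == domain or any(s in subs for s in q.subdomains)]

    def level_members(self, level: OperationalLevel) -> list[Question]:
        return [q for q in self.core_questions if level in q.levels]


@dataclass
class InstrumentSummary:
    """Counts of question items and response codes by level, domain and subdomain."""

    by_level: pd.DataFrame
    by_domain: pd.DataFrame
    by_subdomain: pd.DataFrame
    n_core_questions: int
    n_scoreable_codes: int


def instrument_summary(instr: Instrument) -> InstrumentSummary:
    """Tabulate question-item and response-code counts.

    Domain item counts use domain membership (primary domain plus subdomain
    taps), so a question may be counted under several domains; level counts
    use level listings (primary plus secondary levels).
    """
    level_rows = {}
    for level in OperationalLevel:
        members = instr.level_members(level)
        level_rows[level.value] = {
            "n_questions": len(members),
            "n_scoreable_codes": sum(q.scoreable_count for q in members),
        }
    domain_rows = {}
    for domain in instr.domain_catalogue:
        members = instr.domain_members(domain)
        domain_rows[domain] = {
            "n_question_items": len(members),
            "n_scoreable_codes": sum(q.scoreable_count for q in members),
        }
    sub_rows = {}
    for domain, subs in instr.domain_catalogue.items():
        for s in subs:
            members = [q for q in instr.core_questions if s in q.subdomains]
            sub_rows[s] = {
                "domain": domain,
                "n_question_items": len(members),
                "n_scoreable_codes": sum(q.scoreable_count for q in members),
            }
    return InstrumentSummary(
        by_level=pd.DataFrame.from_dict(level_rows, orient="index"),
        by_domain=pd.DataFrame.from_dict(
            domain_rows, orient="index",
            columns=["n_question_items", "n_scoreable_codes"]),
        by_subdomain=pd.DataFrame.from_dict(
            sub_rows, orient="index",
            columns=["domain", "n_question_items", "n_scoreable_codes"]),
        n_core_questions=instr.n_core_questions,
        n_scoreable_codes=instr.n_scoreable_codes,
    )


# ---------------------------------------------------------------------------
# serialisation

def to_canonical_json(instr: Instrument) -> str:
    """Canonical sorted-key JSON form; byte-stable across round-trips."""
    return json.dumps(instr.model_dump(mode="json"), sort_keys=True, indent=2,
                      ensure_ascii=False) + "\n"


def write_instrument(instr: Instrument, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(to_canonical_json(instr), encoding="utf-8")
    return path


def load_instrument(path: str | Path) -> Instrument:
    """Load and validate an instrument definition (JSON, or YAML surface syntax).

    Raises :class:`InstrumentError` with every violation listed if the file
    fails to parse or any schema invariant is broken; a partially valid
    instrument is never returned.
    """
    path = Path(path)
    if not path.exists():
        raise InstrumentError(f"instrument file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except json.JSONDecodeError as exc:
        raise InstrumentError(
            f"{path}: JSON parse error at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    except yaml.YAMLError as exc:
        raise InstrumentError(f"{path}: YAML parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise InstrumentError(f"{path}: expected a mapping at top level, got {type(raw).__name__}")
    try:
        return Instrument.model_validate(raw)
    except ValidationError as exc:
        issues = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            issues.append(f"{loc or '<root>'}: {err['msg']}")
        raise InstrumentError(
            f"{path}: instrument failed validation with {len(issues)} issue(s)", issues
        ) from exc
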