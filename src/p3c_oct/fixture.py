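"""The bundled default P3C-OCT instrument.

The instrument structure (question count, operational-level allocation,
domain/subdomain catalogue, per-question response-code counts) is encoded
faithfully: 29 core questions listed 11/4/12/4 across the four operational
levels, six domains whose item counts are 6/2/14/6/6/8, and 435 scoreable
response codes in total.  Two questions are listed under a second operational
level (the level allocation sums to 31 listings over 29 distinct questions),
and questions may tap subdomains of more than one domain, which is how the
per-domain item counts sum to 42 over 29 distinct questions.

The full published wording exists only for Q4 (the care-plan checklist, which
is encoded verbatim) and for the sizes of Q1 (eight scoreable codes, "Other"
included) and Q6 (two pooled objective parts, the second on personal
budgets).  Every other activity label is a systematically named placeholder,
flagged ``placeholder: true`` in the serialised file, so it can be replaced
with the published wording without any code change.
"""

from __future__ import annotations

from .instrument import (
    CodeCategory,
    Instrument,
    ObjectivePart,
    OperationalLevel,
    Question,
    QuestionRole,
    ResponseCode,
)

DOMAIN_CATALOGUE: dict[str, list[str]] = {
    "my_goals": [
        "goal_setting",
        "empowerment_and_activation",
        "self_management",
        "carer_support",
    ],
    "decision_making": ["involvement_in_decision_making"],
    "care_planning": [
        "the_care_plan",
        "case_management",
        "single_point_of_contact",
        "care_coordination",
        "supporting_people_to_stay_at_home",
    ],
    "information_and_communication": [
        "relational_continuity",
        "information_gathering_and_sharing",
        "knowledge_of_patient",
    ],
    "transitions": ["continuity_of_care"],
    "organisational_processes": [
        "valuing_physical_and_mental_health_equally",
        "experience_of_care",
        "longer_appointment_times",
        "staff_training",
        "processes_to_address_polypharmacy",
        "p3c_leadership_and_culture_change",
    ],
}

_PP = OperationalLevel.PERSON_PRACTITIONER
_PR = OperationalLevel.PRACTITIONER_PRACTITIONER
_OS = OperationalLevel.ORGANISATIONAL_SYSTEMS
_IS = OperationalLevel.INFORMATION_SYSTEMS

# (question_id, level, secondary levels, primary domain, subdomain taps,
#  scoreable codes per part, prompt)
_CORE_SPEC = [
    ("Q1", _PP, (), "my_goals",
     ["goal_setting", "empowerment_and_activation"], [8],
     "How do you support people to identify and set their own goals for care and support?"),
    ("Q2", _PP, (), "my_goals",
     ["goal_setting"], [16],
     "How are personal goals reviewed and followed up over time?"),
    ("Q3", _PP, (), "my_goals",
     ["empowerment_and_activation", "self_management"], [16],
     "What do you do to build people's confidence and skills to manage their own health?"),
    ("Q4", _PP, (), "care_planning",
     ["the_care_plan"], None,  # verbatim checklist, built below
     "In general, which of the following elements are included in the cocreated plan of "
     "care (this can either be in the form of a written document or a plan of working)?"),
    ("Q5", _PP, (), "decision_making",
     ["involvement_in_decision_making"], [16],
     "How are people involved in decisions about their treatment and care?"),
    ("Q6", _PP, (), "decision_making",
     ["involvement_in_decision_making", "empowerment_and_activation"], [6, 4],
     "What support is available for people to direct their own care, including the use "
     "of personal budgets?"),
    ("Q7", _PP, (), "my_goals",
     ["self_management", "carer_support"], [16],
     "What support do you offer to carers and families to sustain self-management?"),
    ("Q8", _PP, (), "care_planning",
     ["the_care_plan", "case_management"], [16],
     "How are plans of care co-created and recorded with people who could benefit?"),
    ("Q9", _PP, (), "care_planning",
     ["the_care_plan", "supporting_people_to_stay_at_home", "case_management",
      "self_management"], [16],
     "What do you do to support people to remain at home during episodes of ill health?"),
    ("Q10", _PP, (), "information_and_communication",
     ["knowledge_of_patient", "relational_continuity", "continuity_of_care"], [16],
     "How do you ensure the person is known to the practitioners they see?"),
    ("Q11", _PP, (), "transitions",
     ["continuity_of_care", "care_coordination"], [16],
     "How is a person's care kept continuous when their needs or services change?"),
    ("Q12", _PR, (), "care_planning",
     ["care_coordination", "case_management"], [16],
     "How do practitioners within the organisation coordinate care for people with "
     "complex needs?"),
    ("Q13", _PR, (), "care_planning",
     ["case_management", "continuity_of_care"], [16],
     "How is responsibility for a person's ongoing care handed over between practitioners?"),
    ("Q14", _PR, (), "information_and_communication",
     ["information_gathering_and_sharing", "care_coordination"], [16],
     "How is information shared between practitioners involved in the same person's care?"),
    ("Q15", _PR, (), "transitions",
     ["continuity_of_care", "care_coordination"], [16],
     "How do you work with other organisations when people transfer between services?"),
    ("Q16", _OS, (), "care_planning",
     ["case_management", "single_point_of_contact"], [16],
     "What systems identify and track people who could benefit from coordinated care?"),
    ("Q17", _OS, (), "care_planning",
     ["case_management", "single_point_of_contact", "continuity_of_care"], [16],
     "What arrangements give people a consistent point of contact for their care?"),
    ("Q18", _OS, (_IS,), "care_planning",
     ["single_point_of_contact", "care_coordination", "information_gathering_and_sharing"],
     [16],
     "What systems support a single point of contact in a crisis, including out of hours?"),
    ("Q19", _OS, (_IS,), "care_planning",
     ["the_care_plan", "case_management", "information_gathering_and_sharing"], [16],
     "How are plans of care stored and made visible to the teams who need them?"),
    ("Q20", _OS, (), "organisational_processes",
     ["experience_of_care"], [16],
     "How do you measure and act on people's experience of care?"),
    ("Q21", _OS, (), "organisational_processes",
     ["staff_training"], [15],
     "What training do staff receive in person-centred and coordinated ways of working?"),
    ("Q22", _OS, (), "organisational_processes",
     ["longer_appointment_times"], [15],
     "What provision is made for longer appointments for people with complex needs?"),
    ("Q23", _OS, (), "organisational_processes",
     ["processes_to_address_polypharmacy", "valuing_physical_and_mental_health_equally"],
     [15],
     "What processes address polypharmacy and give equal weight to physical and mental "
     "health?"),
    ("Q24", _OS, (), "organisational_processes",
     ["p3c_leadership_and_culture_change"], [15],
     "How does the organisation's leadership promote person-centred coordinated care?"),
    ("Q25", _OS, (), "organisational_processes",
     ["p3c_leadership_and_culture_change"], [15],
     "What dedicated roles or responsibilities exist for leading P3C development?"),
    ("Q26", _OS, (), "organisational_processes",
     ["p3c_leadership_and_culture_change"], [15],
     "How is progress towards person-centred coordinated care reviewed at practice level?"),
    ("Q27", _OS, (), "organisational_processes",
     ["p3c_leadership_and_culture_change", "care_coordination"], [15],
     "How does the organisation work with community and voluntary-sector partners?"),
    ("Q28", _IS, (), "information_and_communication",
     ["information_gathering_and_sharing", "relational_continuity", "care_coordination"],
     [15],
     "What IT systems support shared records across the teams providing care?"),
    ("Q29", _IS, (), "information_and_communication",
     ["information_gathering_and_sharing", "continuity_of_care"], [15],
     "What use is made of telehealth, telecare or telemedicine to support care?"),
]

_Q4_ACTIVITIES = [
    "A lead coordinator",
    "A contingency plan for crisis episodes or exacerbations of their condition",
    "A named person to contact in a crisis",
    "An action plan to attain their health goals",
    "An action plan to attain their social goals",
    "Details of who is responsible for what",
    "A list of medications and instructions for when to take",
    "A date for review",
    "Treatment Escalation Plan",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _marker_codes(qid: str, part_suffix: str, start: int,
                  not_relevant: bool = True) -> list[ResponseCode]:
    codes = [ResponseCode(code_id=f"{qid}.{_LETTERS[start]}", label="None",
                          category=CodeCategory.NONE_MARKER)]
    if not_relevant:
        codes.append(ResponseCode(code_id=f"{qid}.{_LETTERS[start + 1]}",
                                  label="Not relevant",
                                  category=CodeCategory.NOT_RELEVANT_MARKER))
    return codes


def _placeholder_part(qid: str, part_id: str, n_scoreable: int, letter_offset: int = 0,
                      with_other: bool = True, with_not_relevant: bool = True,
                      prompt: str = "") -> ObjectivePart:
    codes: list[ResponseCode] = []
    n_activities = n_scoreable - 1 if with_other else n_scoreable
    for i in range(n_activities):
        letter = _LETTERS[letter_offset + i]
        codes.append(ResponseCode(
            code_id=f"{qid}.{letter}",
            label=f"Placeholder activity {letter} for {qid} "
                  f"(replace with published wording)",
            category=CodeCategory.ACTIVITY,
            placeholder=True,
        ))
    pos = letter_offset + n_activities
    if with_other:
        codes.append(ResponseCode(code_id=f"{qid}.{_LETTERS[pos]}",
                                  label="Other (please specify)",
                                  category=CodeCategory.OTHER))
        pos += 1
    codes.extend(_marker_codes(qid, part_id, pos, not_relevant=with_not_relevant))
    return ObjectivePart(part_id=part_id, prompt=prompt, codes=codes)


def _q4_part() -> ObjectivePart:
    codes = [
        ResponseCode(code_id=f"Q4.{_LETTERS[i]}", label=label,
                     category=CodeCategory.ACTIVITY)
        for i, label in enumerate(_Q4_ACTIVITIES)
    ]
    codes.append(ResponseCode(code_id="Q4.j", label="Other (please specify)",
                              category=CodeCategory.OTHER))
    codes.append(ResponseCode(code_id="Q4.k", label="None",
                              category=CodeCategory.NONE_MARKER))
    codes.append(ResponseCode(code_id="Q4.l", label="Not relevant",
                              category=CodeCategory.NOT_RELEVANT_MARKER))
    return ObjectivePart(part_id="Q4.p1", codes=codes)


def default_instrument() -> Instrument:
    """Build the bundled default instrument (29 core questions, 435 scoreable codes)."""
    questions: list[Question] = []
    for qid, level, secondary, domain, subs, part_sizes, text in _CORE_SPEC:
        if qid == "Q4":
            parts = [_q4_part()]
        elif len(part_sizes) == 1:
            parts = [_placeholder_part(qid, f"{qid}.p1", part_sizes[0])]
        else:
            # Multi-part question: codes are pooled at scoring time.  The
            # second part (personal budgets) has no "Other" box and no
            # "Not relevant" marker of its own.
            parts = [
                _placeholder_part(qid, f"{qid}.p1", part_sizes[0],
                                  prompt="Support for people to direct their own care"),
                _placeholder_part(qid, f"{qid}.p2", part_sizes[1],
                                  letter_offset=part_sizes[0] + 2,
                                  with_other=False, with_not_relevant=False,
                                  prompt="Use of personal budgets"),
            ]
        questions.append(Question(
            question_id=qid, text=text, role=QuestionRole.CORE,
            operational_level=level, secondary_levels=list(secondary),
            domain=domain, subdomains=subs, parts=parts, has_likert=True,
        ))
    questions.append(Question(
        question_id="R1",
        text="Please reflect on how useful you found completing this tool.",
        role=QuestionRole.REFLECTIVE_TEXTBOX,
    ))
    questions.append(Question(
        question_id="R2",
        text="Please suggest any changes that would improve the tool.",
        role=QuestionRole.REFLECTIVE_TEXTBOX,
    ))
    for did, dtext in [
        ("D1", "Practice list size (number of registered patients)."),
        ("D2", "Setting (rural / suburban / urban)."),
        ("D3", "Number of whole-time-equivalent clinical staff."),
    ]:
        questions.append(Question(question_id=did, text=dtext,
                                  role=QuestionRole.DEMOGRAPHIC))
    return Instrument(
        name="P3C-OCT",
        version="1.0",
        questions=questions,
        domain_catalogue=DOMAIN_CATALOGUE,
        notes=[
            "Q18 and Q19 are double-listed under information_systems, so the four "
            "level listings sum to 31 over 29 distinct core questions.",
            "Activity labels flagged placeholder=true stand in for unpublished "
            "wording and can be replaced without code changes.",
        ],
    )
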