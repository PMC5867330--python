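"""Schema validation, canonical serialisation and the bundled instrument's
printed structure."""

import pytest

from p3c_oct import (
    Instrument,
    InstrumentError,
    instrument_summary,
    load_instrument,
    to_canonical_json,
    write_instrument,
)
from p3c_oct.instrument import CodeCategory

from tests.helpers import make_instrument


class TestBundledStructure:
    def test_core_question_count(self, instrument):
        assert instrument.n_core_questions == 29

    def test_level_listing_counts(self, instrument):
        by_level = instrument_summary(instrument).by_level["n_questions"]
        assert by_level["person_practitioner"] == 11
        assert by_level["practitioner_practitioner"] == 4
        assert by_level["organisational_systems"] == 12
        assert by_level["information_systems"] == 4

    def test_domain_item_counts(self, instrument):
        by_domain = instrument_summary(instrument).by_domain["n_question_items"]
        expected = {
            "my_goals": 6,
            "decision_making": 2,
            "care_planning": 14,
            "information_and_communication": 6,
            "transitions": 6,
            "organisational_processes": 8,
        }
        assert by_domain.to_dict() == expected

    def test_subdomain_item_counts(self, instrument):
        by_sub = instrument_summary(instrument).by_subdomain["n_question_items"]
        expected = {
            "goal_setting": 2, "empowerment_and_activation": 3,
            "self_management": 3, "carer_support": 1,
            "involvement_in_decision_making": 2,
            "the_care_plan": 4, "case_management": 7,
            "single_point_of_contact": 3, "care_coordination": 7,
            "supporting_people_to_stay_at_home": 1,
            "relational_continuity": 2, "information_gathering_and_sharing": 5,
            "knowledge_of_patient": 1,
            "continuity_of_care": 6,
            "valuing_physical_and_mental_health_equally": 1,
            "experience_of_care": 1, "longer_appointment_times": 1,
            "staff_training": 1, "processes_to_address_polypharmacy": 1,
            "p3c_leadership_and_culture_change": 4,
        }
        assert by_sub.to_dict() == expected

    def test_total_scoreable_codes(self, instrument):
        assert instrument.n_scoreable_codes == 435

    def test_q4_encoded_verbatim(self, instrument):
        q4 = instrument.get_question("Q4")
        assert q4.scoreable_count == 10  # nine named elements plus "Other"
        labels = [c.label for p in q4.parts for c in p.codes]
        assert "A named person to contact in a crisis" in labels
        assert "Treatment Escalation Plan" in labels
        assert not any(c.placeholder for p in q4.parts for c in p.codes)

    def test_q1_has_eight_scoreable_codes(self, instrument):
        q1 = instrument.get_question("Q1")
        assert q1.scoreable_count == 8
        assert len(q1.other_ids) == 1  # the "Other" box counts among the eight

    def test_q6_pools_two_parts(self, instrument):
        q6 = instrument.get_question("Q6")
        assert len(q6.parts) == 2
        assert [p.scoreable_count for p in q6.parts] == [6, 4]
        assert q6.scoreable_count == 10

    def test_non_core_questions_present(self, instrument):
        roles = [q.role.value for q in instrument.questions]
        assert roles.count("reflective_textbox") == 2
        assert roles.count("demographic") == 3


class TestSerialisation:
    def test_round_trip_is_byte_stable(self, instrument, tmp_path):
        p1 = write_instrument(instrument, tmp_path / "a.json")
        loaded = load_instrument(p1)
        p2 = write_instrument(loaded, tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_structure(self, instrument, tmp_path):
        loaded = load_instrument(write_instrument(instrument, tmp_path / "i.json"))
        assert loaded == instrument

    def test_yaml_surface_accepted(self, instrument, tmp_path):
        import yaml
        path = tmp_path / "i.yaml"
        path.write_text(yaml.safe_dump(instrument.model_dump(mode="json")))
        assert load_instrument(path) == instrument

    def test_parse_error_names_location(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"name": "x", ')
        with pytest.raises(InstrumentError, match="line"):
            load_instrument(path)


class TestValidation:
    def test_missing_none_marker_rejected(self, instrument, tmp_path):
        raw = instrument.model_dump(mode="json")
        part = raw["questions"][0]["parts"][0]
        part["codes"] = [c for c in part["codes"]
                         if c["category"] != "none_marker"]
        path = tmp_path / "bad.json"
        import json
        path.write_text(json.dumps(raw))
        with pytest.raises(InstrumentError, match="none_marker"):
            load_instrument(path)

    def test_all_violations_listed(self, instrument, tmp_path):
        raw = instrument.model_dump(mode="json")
        # break two independent invariants in two different questions
        raw["questions"][0]["parts"][0]["codes"] = [
            c for c in raw["questions"][0]["parts"][0]["codes"]
            if c["category"] != "none_marker"]
        raw["questions"][1]["has_likert"] = False
        path = tmp_path / "bad2.json"
        import json
        path.write_text(json.dumps(raw))
        with pytest.raises(InstrumentError) as exc_info:
            load_instrument(path)
        assert len(exc_info.value.issues) >= 2

    def test_duplicate_code_ids_rejected(self):
        with pytest.raises(Exception, match="duplicate"):
            from p3c_oct.instrument import ObjectivePart, ResponseCode
            ObjectivePart(part_id="p", codes=[
                ResponseCode(code_id="x", label="a",
                             category=CodeCategory.ACTIVITY),
                ResponseCode(code_id="x", label="b",
                             category=CodeCategory.ACTIVITY),
                ResponseCode(code_id="n", label="None",
                             category=CodeCategory.NONE_MARKER),
            ])

    def test_unknown_subdomain_rejected(self):
        from tests.helpers import make_question
        q = make_question("Q1", [3], subdomains=["nonexistent"])
        with pytest.raises(Exception, match="unknown subdomain"):
            Instrument(name="x", version="0", questions=[q],
                       domain_catalogue={"d1": ["s1"]})


class TestSummary:
    def test_empty_instrument_all_counts_zero(self):
        instr = Instrument(name="empty", version="0", questions=[],
                           domain_catalogue={"d1": ["s1"]})
        s = instrument_summary(instr)
        assert s.n_core_questions == 0
        assert s.n_scoreable_codes == 0
        assert (s.by_level["n_questions"] == 0).all()
        assert (s.by_domain["n_question_items"] == 0).all()

    def test_counts_sum_to_instrument_totals(self, instrument):
        s = instrument_summary(instrument)
        # level listings exceed the distinct count by the two double-listed
        # questions; domain items sum to the printed 42 over 29 questions
        assert s.by_level["n_questions"].sum() == 31
        assert s.by_domain["n_question_items"].sum() == 42

    def test_tiny_instrument_counts(self):
        instr = make_instrument([[3], [5, 2]])
        s = instrument_summary(instr)
        assert s.n_core_questions == 2
        assert s.n_scoreable_codes == 10
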