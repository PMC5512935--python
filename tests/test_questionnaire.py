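"""Questionnaire schema, branch relabeling, and file-dialect round trips."""

import json

import pytest

from ftree.fixtures import random_questionnaire, scenario_questionnaire
from ftree.questionnaire import (
    PersonRecord,
    Questionnaire,
    QuestionnaireError,
    blank_questionnaire,
    questionnaire_to_json,
    read_questionnaire,
    relationship_slots,
    write_questionnaire,
)


class TestSlots:
    def test_branch_changes_labels_only(self):
        with_child = relationship_slots(True)
        without = relationship_slots(False)
        assert [s.slot_id for s in with_child] == [s.slot_id for s in without]
        assert len(with_child) == len(without)

    @pytest.mark.parametrize("slot_id,with_label,without_label", [
        ("his_parents", "Husband's (his) parents", "Paternal grandparents"),
        ("her_parents", "Wife's (her) parents", "Maternal grandparents"),
        ("his_siblings", "His siblings", "Paternal uncles/aunts"),
        ("her_siblings", "Her siblings", "Maternal uncles/aunts"),
        ("his_paternal_uncles_aunts", "His paternal uncles/aunts",
         "Siblings of paternal grandfather"),
        ("her_maternal_uncles_aunts", "Her maternal uncles/aunts",
         "Siblings of maternal grandmother"),
        ("his_divorced_partners", "His divorced partners",
         "Divorced partners of father"),
        ("child", "Children of client couple", "Client (consultand)"),
    ])
    def test_correspondence_labels(self, slot_id, with_label, without_label):
        by_id = {s.slot_id: s for s in relationship_slots(True)}
        assert by_id[slot_id].label(True) == with_label
        assert by_id[slot_id].label(False) == without_label

    def test_repeated_slots_carry_birth_order_index(self):
        by_id = {s.slot_id: s for s in relationship_slots(True)}
        assert by_id["child"].member_label(True, 2).endswith("#2")


class TestBlankQuestionnaire:
    @pytest.mark.parametrize("has_child", [True, False])
    def test_defaults(self, has_child):
        q = blank_questionnaire(has_child)
        assert len(q.key_table.entries) == 16
        assert all(not e.checked for e in q.key_table.entries)
        assert not any(r.is_proband for r in q.all_records())
        # every record's name is its relationship label
        for r in q.all_records():
            assert r.name == r.default_name(has_child)
            assert r.is_blank(has_child)

    def test_client_couple_member_labels(self):
        q = blank_questionnaire(True)
        assert q.record("client").name == "Client (consultand) couple (husband)"
        assert q.record("spouse").name == "Client (consultand) couple (wife)"

    def test_name_equal_to_default_label_is_unset(self):
        q = blank_questionnaire(True)
        rec = q.record("client")
        assert rec.effective_name(True) == ""
        rec.name = "Taro"
        assert rec.effective_name(True) == "Taro"


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["json", "csv"])
    @pytest.mark.parametrize("seed", range(25))
    def test_random_questionnaires(self, fmt, seed):
        q = random_questionnaire(seed)
        text = write_questionnaire(q, fmt)
        q2 = read_questionnaire(text, fmt)
        # write . read = identity (byte level) and read . write = identity
        assert write_questionnaire(q2, fmt) == text
        assert questionnaire_to_json(q2) == questionnaire_to_json(q)

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    @pytest.mark.parametrize("name", ["D", "P", "VHL", "ultimate", "minimal"])
    def test_scenarios(self, fmt, name):
        q = scenario_questionnaire(name)
        text = write_questionnaire(q, fmt)
        assert questionnaire_to_json(read_questionnaire(text, fmt)) == \
            questionnaire_to_json(q)

    def test_output_is_deterministic(self):
        a = write_questionnaire(scenario_questionnaire("ultimate"), "json")
        b = write_questionnaire(scenario_questionnaire("ultimate"), "json")
        assert a == b


class TestSchemaErrors:
    def test_minimal_json(self):
        q = read_questionnaire(
            '{"client_has_child": false, "records": {"client": {"sex": "female"}}}',
            "json")
        assert q.client_has_child is False
        assert q.record("client").sex.value == "female"
        assert len([r for r in q.all_records()
                    if not r.is_blank(False)]) == 1

    def test_unknown_field_rejected(self):
        with pytest.raises(QuestionnaireError, match="unknown fields"):
            read_questionnaire(
                '{"client_has_child": true, '
                '"records": {"client": {"shoe_size": 42}}}', "json")

    def test_unknown_slot_rejected(self):
        with pytest.raises(QuestionnaireError, match="unknown relationship"):
            read_questionnaire(
                '{"client_has_child": true, "records": {"cousin_thrice": {}}}',
                "json")

    def test_monozygotic_requires_gestation_id(self):
        q = Questionnaire(client_has_child=True)
        q.put(PersonRecord(slot_id="child", index=1, monozygotic=True))
        with pytest.raises(QuestionnaireError, match="Multiple-gestation"):
            write_questionnaire(q, "csv")

    def test_monozygotic_without_gestation_id_in_csv(self):
        import csv as _csv
        import io

        from ftree.questionnaire import CSV_HEADER

        text = write_questionnaire(scenario_questionnaire("ultimate"), "csv")
        rows = list(_csv.reader(io.StringIO(text)))
        gid_col = CSV_HEADER.index("multiple_gestation_id")
        mono_col = CSV_HEADER.index("monozygotic")
        for row in rows[1:]:
            if row[0] == "record" and row[mono_col] == "yes":
                row[gid_col] = ""  # Monozygotic checked, gestation ID blank
        buf = io.StringIO()
        _csv.writer(buf, lineterminator="\n").writerows(rows)
        with pytest.raises(QuestionnaireError,
                           match="Multiple-gestation"):
            read_questionnaire(buf.getvalue(), "csv")

    def test_overlay_requires_consanguinity_box(self):
        q = Questionnaire(client_has_child=True)
        q.put(PersonRecord(slot_id="spouse", overlay_id=3))
        with pytest.raises(QuestionnaireError, match="Consanguinity"):
            write_questionnaire(q, "json")

    def test_two_probands_rejected(self):
        q = Questionnaire(client_has_child=True)
        q.put(PersonRecord(slot_id="client", is_proband=True))
        q.put(PersonRecord(slot_id="spouse", is_proband=True))
        with pytest.raises(QuestionnaireError, match="proband"):
            write_questionnaire(q, "json")

    def test_unsupported_version(self):
        doc = json.loads(write_questionnaire(blank_questionnaire(True)))
        doc["format_version"] = "9.9"
        with pytest.raises(QuestionnaireError, match="format_version"):
            read_questionnaire(json.dumps(doc), "json")

    def test_csv_error_names_row(self):
        text = write_questionnaire(scenario_questionnaire("D"), "csv")
        broken = text.replace(",male,", ",malformed,", 1)
        with pytest.raises(QuestionnaireError, match="row"):
            read_questionnaire(broken, "csv")
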