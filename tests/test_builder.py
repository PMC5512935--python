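"""Questionnaire-to-pedigree construction, numbering, overlay, comments."""

import warnings

import pytest

from ftree.builder import (
    BuildError,
    OverlayError,
    OverlayWarning,
    apply_overlay,
    assign_identifiers,
    attach_comment,
    build_pedigree,
    detach_comment,
)
from ftree.docio import pedigree_to_json
from ftree.fixtures import random_questionnaire, scenario_questionnaire
from ftree.model import (
    LifeStage,
    N_UNKNOWN,
    Sex,
    UnionStatus,
    Zygosity,
    generation_count,
    validate_pedigree,
)
from ftree.questionnaire import (
    AgeValue,
    PersonRecord,
    Questionnaire,
    blank_questionnaire,
)


def family_q(**client_kw):
    """Client couple + 2 children + both parent pairs."""
    q = Questionnaire(client_has_child=True)
    q.put(PersonRecord(slot_id="client", sex=Sex.MALE, age=AgeValue.of(40),
                       **client_kw))
    q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE, age=AgeValue.of(38)))
    q.put(PersonRecord(slot_id="child", index=1, sex=Sex.MALE,
                       age=AgeValue.of(10)))
    q.put(PersonRecord(slot_id="child", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(8)))
    for slot in ("his_parents", "her_parents"):
        q.put(PersonRecord(slot_id=slot, index=1, sex=Sex.MALE,
                           age=AgeValue.of(70)))
        q.put(PersonRecord(slot_id=slot, index=2, sex=Sex.FEMALE,
                           age=AgeValue.of(68)))
    return q


class TestGenerationPlacement:
    def test_client_with_children_sits_in_generation_2(self):
        p = build_pedigree(family_q())
        gens = sorted({i.generation for i in p.individuals.values()})
        assert gens == [1, 2, 3]
        client = next(i for i in p.individuals.values()
                      if i.sex == Sex.MALE and i.age.years == 40)
        assert client.generation == 2

    def test_client_without_children_sits_in_generation_3(self):
        q = Questionnaire(client_has_child=False)
        q.put(PersonRecord(slot_id="child", index=1, sex=Sex.FEMALE,
                           is_consultand=True))
        p = build_pedigree(q)
        assert len(p.individuals) == 1
        assert next(iter(p.individuals.values())).generation == 3

    def test_blank_sheet_builds_mandatory_nodes_only(self):
        assert len(build_pedigree(blank_questionnaire(True)).individuals) == 2
        assert len(build_pedigree(blank_questionnaire(False)).individuals) == 1

    def test_generations_never_exceed_three(self):
        for seed in range(50):
            p = build_pedigree(random_questionnaire(seed))
            assert generation_count(p) <= 3


class TestStructure:
    def test_shared_gestation_id_forms_twin_group(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=1, sex=Sex.MALE,
                           multiple_gestation_id=1, monozygotic=True))
        q.put(PersonRecord(slot_id="child", index=2, sex=Sex.MALE,
                           multiple_gestation_id=1, monozygotic=True))
        p = build_pedigree(q)
        groups = [tg for s in p.sibships.values() for tg in s.twin_groups]
        assert len(groups) == 1
        assert groups[0].zygosity == Zygosity.MONOZYGOTIC
        assert len(groups[0].members) == 2

    def test_pair_without_monozygotic_box_is_dizygotic(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=1, sex=Sex.MALE,
                           multiple_gestation_id=1))
        q.put(PersonRecord(slot_id="child", index=2, sex=Sex.FEMALE,
                           multiple_gestation_id=1))
        groups = [tg for s in build_pedigree(q).sibships.values()
                  for tg in s.twin_groups]
        assert groups[0].zygosity == Zygosity.DIZYGOTIC

    def test_n_unknown_multiple_individuals(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=3,
                           multiple_individuals=N_UNKNOWN))
        p = build_pedigree(q)
        assert any(i.multiple_count == N_UNKNOWN
                   for i in p.individuals.values())

    def test_siblings_materialize_connector_parents(self):
        q = Questionnaire(client_has_child=True)
        q.put(PersonRecord(slot_id="his_siblings", index=1, sex=Sex.FEMALE))
        p = build_pedigree(q)
        # client couple + sibling + two unnamed history-unknown parents
        connectors = [i for i in p.individuals.values() if i.history_unknown]
        assert len(connectors) == 2
        assert {c.sex for c in connectors} == {Sex.MALE, Sex.FEMALE}
        assert all(c.name == "" for c in connectors)

    def test_divorced_partner_union_and_custody(self):
        q = family_q()
        q.put(PersonRecord(slot_id="his_divorced_partners", index=1,
                           sex=Sex.FEMALE))
        q.put(PersonRecord(slot_id="child", index=3, sex=Sex.MALE,
                           of_divorced_partner=1, divorced_side="his",
                           custody_flag=True))
        p = build_pedigree(q)
        divorced = [u for u in p.unions.values()
                    if u.status == UnionStatus.DIVORCED]
        assert len(divorced) == 1
        assert divorced[0].custody.value in ("partner_a", "partner_b")
        sib = p.sibship_of_union(divorced[0].id)
        assert len(sib.children) == 1

    def test_second_divorced_partner_rejected(self):
        q = family_q()
        q.put(PersonRecord(slot_id="his_divorced_partners", index=1,
                           sex=Sex.FEMALE))
        q.put(PersonRecord(slot_id="his_divorced_partners", index=2,
                           sex=Sex.FEMALE))
        with pytest.raises(BuildError, match="divorced partner"):
            build_pedigree(q)

    def test_pregnancy_on_deceased_rejected(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=3, pregnancy=True,
                           general_status=["deceased"]))
        with pytest.raises(BuildError, match="deceased"):
            build_pedigree(q)

    def test_stillbirth_and_ectopic_get_auto_annotations(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=3,
                           fetal_status="stillbirth"))
        q.put(PersonRecord(slot_id="child", index=4, fetal_status="ectopic"))
        p = build_pedigree(q)
        notes = {a for i in p.individuals.values() for a in i.annotations}
        assert {"SB", "ECT"} <= notes

    def test_affected_record_without_keys_uses_base_key(self):
        q = family_q()
        q.put(PersonRecord(slot_id="child", index=1, sex=Sex.MALE,
                           general_status=["affected"]))
        p = build_pedigree(q)
        affected = [i for i in p.individuals.values() if i.affected]
        assert affected and all(i.condition_keys == [1] for i in affected)


class TestIdentifiers:
    def test_topmost_leftmost_is_I_1(self, d_pedigree):
        top = [i for i in d_pedigree.individuals.values()
               if i.gen_label == "I"]
        assert min(i.number for i in top) == 1
        assert all(i.number >= 1 for i in top)

    def test_single_individual_is_I_1(self):
        q = Questionnaire(client_has_child=False)
        p = build_pedigree(q)
        assert [i.label for i in p.individuals.values()] == ["I-1"]

    @pytest.mark.parametrize("name", ["D", "P", "VHL", "ultimate"])
    def test_numbering_gap_free_per_generation(self, name):
        # brute-force: within each generation the labels are exactly 1..k
        p = build_pedigree(scenario_questionnaire(name))
        per_gen = {}
        for i in p.individuals.values():
            per_gen.setdefault(i.gen_label, []).append(i.number)
        for label, numbers in per_gen.items():
            assert sorted(numbers) == list(range(1, len(numbers) + 1)), label


class TestDeterminism:
    @pytest.mark.parametrize("name", ["D", "P", "ultimate"])
    def test_identical_questionnaires_build_identical_pedigrees(self, name):
        a = pedigree_to_json(build_pedigree(scenario_questionnaire(name)))
        b = pedigree_to_json(build_pedigree(scenario_questionnaire(name)))
        assert a == b

    def test_random_questionnaires_build_validate_clean(self):
        for seed in range(150):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OverlayWarning)
                p = build_pedigree(random_questionnaire(seed))
            errors = [v for v in validate_pedigree(p)
                      if v.severity == "error"]
            assert errors == [], f"seed {seed}: {errors}"


class TestOverlay:
    def test_fuses_pair_and_marks_union(self, p_pedigree):
        consang = [u for u in p_pedigree.unions.values() if u.consanguineous]
        assert len(consang) == 1

    def test_individual_count_decreases_by_one(self, p_questionnaire):
        # disable the overlay by dropping the ids: two separate individuals
        q = p_questionnaire
        n_records = len([r for r in q.all_records() if not r.is_blank(True)])
        p = build_pedigree(q)
        # one fewer individual than non-blank records (pair fused), plus the
        # uncle's materialized spouse connector
        connectors = [i for i in p.individuals.values()
                      if i.history_unknown and not i.name]
        assert len(p.individuals) == n_records - 1 + len(connectors)

    def test_no_groups_is_identity(self, d_pedigree):
        before = pedigree_to_json(d_pedigree)
        assert pedigree_to_json(apply_overlay(d_pedigree, [])) == before

    def test_merged_attributes_prefer_entered_values(self, p_pedigree):
        merged = next(i for i in p_pedigree.individuals.values()
                      if i.name == "Mika")
        assert merged.sex == Sex.FEMALE
        assert merged.is_consultand  # from the spouse-slot record
        assert merged.carrier        # from the cousin record

    def test_conflicting_sex_rejected(self):
        q = scenario_questionnaire("P")
        q.record("spouse").sex = Sex.MALE
        with pytest.raises(OverlayError, match="sex"):
            build_pedigree(q)

    def test_overlay_id_on_one_record_rejected(self):
        q = scenario_questionnaire("P")
        q.record("his_paternal_cousins").overlay_id = None
        q.record("his_paternal_cousins").consanguinity_flag = False
        with pytest.raises(BuildError, match="exactly 2"):
            build_pedigree(q)

    def test_non_first_cousin_fusion_warns(self):
        # fuse the spouse with the husband's sibling's record: consanguineous
        # but not first cousins
        q = Questionnaire(client_has_child=True)
        q.put(PersonRecord(slot_id="client", sex=Sex.MALE))
        q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE,
                           consanguinity_flag=True, overlay_id=1))
        q.put(PersonRecord(slot_id="his_siblings", index=1, sex=Sex.FEMALE,
                           consanguinity_flag=True, overlay_id=1))
        with pytest.warns(OverlayWarning):
            p = build_pedigree(q)
        assert any(u.consanguineous for u in p.unions.values())


class TestComments:
    def test_attach_then_detach_restores_pedigree(self, d_pedigree):
        before = pedigree_to_json(d_pedigree)
        attach_comment(d_pedigree, "i1", "severe phenotype")
        cid = d_pedigree.comments[0].id
        detach_comment(d_pedigree, cid)
        assert pedigree_to_json(d_pedigree) == before

    def test_comments_keep_insertion_order(self, d_pedigree):
        attach_comment(d_pedigree, "i1", "first")
        attach_comment(d_pedigree, (120.0, 40.0), "second")
        assert [c.text for c in d_pedigree.comments] == ["first", "second"]

    def test_unknown_target_and_id_raise(self, d_pedigree):
        from ftree.builder import PedigreeCommentError
        with pytest.raises(PedigreeCommentError):
            attach_comment(d_pedigree, "ghost", "x")
        with pytest.raises(PedigreeCommentError):
            detach_comment(d_pedigree, "c99")
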