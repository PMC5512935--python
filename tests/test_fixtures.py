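"""Scenario fixtures, the random generator, and concordance scoring."""

import math
import warnings

import pytest

from ftree.builder import OverlayWarning, build_pedigree
from ftree.fixtures import (
    SCENARIOS,
    random_questionnaire,
    scenario_questionnaire,
    score_concordance,
)
from ftree.layout import compute_layout, overlap_audit
from ftree.model import LifeStage, Sex, generation_count, validate_pedigree
from ftree.questionnaire import questionnaire_to_json
from ftree.render import render_svg


class TestScenarios:
    @pytest.mark.parametrize("name", SCENARIOS)
    def test_full_pipeline_clean(self, name):
        q = scenario_questionnaire(name)
        p = build_pedigree(q)
        assert [v for v in validate_pedigree(p) if v.severity == "error"] == []
        lay = compute_layout(p)
        assert overlap_audit(lay) == []
        svg = render_svg(lay, p)
        assert svg.startswith("<?xml")

    @pytest.mark.parametrize("name", SCENARIOS)
    def test_deterministic(self, name):
        a = questionnaire_to_json(scenario_questionnaire(name))
        b = questionnaire_to_json(scenario_questionnaire(name))
        assert a == b

    def test_minimal_is_a_lone_third_generation_client(self):
        p = build_pedigree(scenario_questionnaire("minimal"))
        assert len(p.individuals) == 1
        assert next(iter(p.individuals.values())).generation == 3

    def test_d_shows_an_x_linked_pattern(self):
        # affected individuals are all male; carriers all female
        p = build_pedigree(scenario_questionnaire("D"))
        affected = [i for i in p.individuals.values() if i.affected]
        carriers = [i for i in p.individuals.values() if i.carrier]
        assert affected and carriers
        assert all(i.sex == Sex.MALE for i in affected)
        assert all(i.sex == Sex.FEMALE for i in carriers)

    def test_p_has_exactly_one_consanguineous_union(self, p_pedigree):
        assert sum(u.consanguineous
                   for u in p_pedigree.unions.values()) == 1
        # recessive pattern: affected child of two carrier parents
        proband = p_pedigree.individuals[p_pedigree.proband_id]
        parents = [p_pedigree.individuals[x]
                   for x in p_pedigree.parents_of(proband.id)]
        assert proband.affected
        assert all(x.carrier for x in parents)

    def test_vhl_dominant_chain_across_three_generations(self):
        p = build_pedigree(scenario_questionnaire("VHL"))
        affected_gens = {i.generation for i in p.individuals.values()
                         if i.affected}
        assert affected_gens == {1, 2, 3}

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_questionnaire("Q")


class TestRandomQuestionnaire:
    def test_same_seed_same_questionnaire(self):
        a = questionnaire_to_json(random_questionnaire(7))
        b = questionnaire_to_json(random_questionnaire(7))
        assert a == b

    def test_zero_affected_rate_gives_no_affected(self):
        for seed in range(40):
            q = random_questionnaire(seed, affected_rate=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OverlayWarning)
                p = build_pedigree(q)
            assert not any(i.affected for i in p.individuals.values())

    def test_twin_rate_realized_within_sampling_error(self):
        rate, n = 0.5, 400
        hits = eligible = 0
        for seed in range(n):
            q = random_questionnaire(seed, twin_rate=rate)
            children = q.records.get("child", [])
            if len(children) >= 2:  # a pair is only possible with >= 2 kids
                eligible += 1
                if any(r.multiple_gestation_id is not None for r in children):
                    hits += 1
        se = math.sqrt(rate * (1 - rate) / eligible)
        assert abs(hits / eligible - rate) < 3 * se

    def test_builder_never_rejects_generator_output(self):
        for seed in range(300):
            q = random_questionnaire(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OverlayWarning)
                p = build_pedigree(q)
            assert generation_count(p) <= 3

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            random_questionnaire(0, twin_rate=1.5)


class TestConcordance:
    def test_identical_pedigrees_score_one(self, d_pedigree):
        other = build_pedigree(scenario_questionnaire("D"))
        score = score_concordance(d_pedigree, other)
        assert score.fraction == 1.0
        assert score.matched_elements == score.total_elements

    def test_empty_candidate_scores_zero(self, d_pedigree):
        from ftree.model import Pedigree
        score = score_concordance(Pedigree(), d_pedigree)
        assert score.fraction == 0.0

    def test_one_sex_flip_costs_exactly_one_point(self):
        # brute-force count on a minimal couple fixture
        ref = build_pedigree(scenario_questionnaire("D"))
        cand = build_pedigree(scenario_questionnaire("D"))
        flip = next(i for i in cand.individuals.values()
                    if i.sex == Sex.MALE and i.generation == 3)
        flip.sex = Sex.FEMALE
        score = score_concordance(cand, ref)
        assert score.matched_elements == score.total_elements - 1

    def test_invariant_to_id_relabeling(self, d_pedigree):
        import copy
        relabeled = copy.deepcopy(d_pedigree)
        mapping = {iid: f"z{k}" for k, iid in enumerate(relabeled.individuals)}
        relabeled.individuals = {
            mapping[iid]: ind for iid, ind in relabeled.individuals.items()}
        for iid, ind in relabeled.individuals.items():
            ind.id = iid
        for u in relabeled.unions.values():
            u.partner_a = mapping[u.partner_a]
            u.partner_b = mapping[u.partner_b]
        for s in relabeled.sibships.values():
            s.children = [mapping[c] for c in s.children]
            for tg in s.twin_groups:
                tg.members = [mapping[m] for m in tg.members]
        relabeled.proband_id = mapping[relabeled.proband_id]
        relabeled.consultand_ids = [mapping[c]
                                    for c in relabeled.consultand_ids]
        assert score_concordance(relabeled, d_pedigree).fraction == 1.0

    def test_breakdown_accounts_for_all_elements(self, p_pedigree):
        ref = build_pedigree(scenario_questionnaire("P"))
        score = score_concordance(p_pedigree, ref)
        assert sum(t for _, t in score.element_breakdown.values()) == \
            score.total_elements
        assert sum(m for m, _ in score.element_breakdown.values()) == \
            score.matched_elements
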