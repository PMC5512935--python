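"""Deterministic scenario questionnaires, randomized questionnaires, and a
pedigree concordance scorer.

The named scenarios are synthetic family histories authored to the stated
inheritance patterns — they are representative fixtures, not transcriptions
of any real family:

* ``D`` — an X-linked condition (Duchenne muscular dystrophy): affected males
  related through unaffected carrier females.
* ``P`` — an autosomal-recessive condition (phenylketonuria) with a
  first-cousin marriage entered through the consanguinity overlay.
* ``VHL`` — a three-generation autosomal-dominant family (von Hippel-Lindau
  syndrome), client in the third generation.
* ``ultimate`` — a maximal chart exercising twins, pregnancy outcomes,
  adoption, donors, divorce/custody, childless unions and more at once.
* ``minimal`` — a lone client with no relations entered.

Concordance scoring weights every structural element equally (one point
each); the breakdown reports per-category counts so alternative weightings
can be layered on top.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date

from .layout import generation_orders
from .model import (
    AgeValue,
    GestationalAge,
    N_UNKNOWN,
    Pedigree,
    PedigreeMetadata,
    Sex,
    occupied_levels,
)
from .questionnaire import (
    PersonRecord,
    Questionnaire,
    blank_questionnaire,
)

SCENARIOS = ("D", "P", "VHL", "ultimate", "minimal")


# ---------------------------------------------------------------------------
# named scenarios


def _scenario_d() -> Questionnaire:
    q = Questionnaire(client_has_child=True, metadata=PedigreeMetadata(
        family_names="scenario D (synthetic)",
        reason_for_pedigree="X-linked condition in the family",
        date_of_intake=date(2017, 7, 14)))
    q.key_table.entry(1).label = "Duchenne muscular dystrophy"
    q.key_table.entry(1).checked = True
    q.put(PersonRecord(slot_id="client", name="Taro", age=AgeValue.of(36),
                       sex=Sex.MALE))
    q.put(PersonRecord(slot_id="spouse", name="Hanako", age=AgeValue.of(33),
                       sex=Sex.FEMALE, general_status=["carrier"],
                       is_consultand=True))
    q.put(PersonRecord(slot_id="child", index=1, name="Ichiro",
                       sex=Sex.MALE, age=AgeValue.of(6),
                       general_status=["affected"], condition_key_refs=[1],
                       is_proband=True))
    q.put(PersonRecord(slot_id="child", index=2, name="Yuki",
                       sex=Sex.FEMALE, age=AgeValue.of(3)))
    q.put(PersonRecord(slot_id="her_parents", index=1, sex=Sex.MALE,
                       age=AgeValue.of(61)))
    q.put(PersonRecord(slot_id="her_parents", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(58), general_status=["carrier"]))
    q.put(PersonRecord(slot_id="her_siblings", index=1, sex=Sex.MALE,
                       age=AgeValue.of(30), general_status=["affected",
                                                            "deceased"],
                       condition_key_refs=[1]))
    return q


def _scenario_p() -> Questionnaire:
    q = Questionnaire(client_has_child=True, metadata=PedigreeMetadata(
        family_names="scenario P (synthetic)",
        reason_for_pedigree="autosomal-recessive condition, consanguineous "
                            "marriage",
        date_of_intake=date(2017, 7, 14)))
    q.key_table.entry(1).label = "Phenylketonuria"
    q.key_table.entry(1).checked = True
    q.put(PersonRecord(slot_id="client", name="Kenji", age=AgeValue.of(31),
                       sex=Sex.MALE, general_status=["carrier"]))
    # the wife is entered twice: minimally on the client branch, fully as the
    # paternal uncle's daughter; the overlay fuses the two records
    q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE, is_consultand=True,
                       consanguinity_flag=True, overlay_id=1))
    q.put(PersonRecord(slot_id="his_parents", index=1, sex=Sex.MALE,
                       age=AgeValue.of(60)))
    q.put(PersonRecord(slot_id="his_parents", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(57)))
    q.put(PersonRecord(slot_id="his_paternal_uncles_aunts", index=1,
                       sex=Sex.MALE, age=AgeValue.of(63)))
    q.put(PersonRecord(slot_id="his_paternal_cousins", index=1,
                       parent_index=1, name="Mika", sex=Sex.FEMALE,
                       age=AgeValue.of(29), general_status=["carrier"],
                       consanguinity_flag=True, overlay_id=1))
    q.put(PersonRecord(slot_id="child", index=1, sex=Sex.FEMALE,
                       age=AgeValue.of(2), general_status=["affected"],
                       condition_key_refs=[1], is_proband=True))
    q.put(PersonRecord(slot_id="child", index=2, sex=Sex.MALE,
                       age=AgeValue.unknown()))
    return q


def _scenario_vhl() -> Questionnaire:
    q = Questionnaire(client_has_child=False, metadata=PedigreeMetadata(
        family_names="scenario VHL (synthetic)",
        reason_for_pedigree="autosomal-dominant condition",
        date_of_intake=date(2017, 7, 14)))
    q.key_table.entry(1).label = "von Hippel-Lindau syndrome"
    q.key_table.entry(1).checked = True
    # central couple = parents of the client under the no-child branch
    q.put(PersonRecord(slot_id="client", sex=Sex.MALE, age=AgeValue.of(55),
                       general_status=["affected"], condition_key_refs=[1]))
    q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE, age=AgeValue.of(54)))
    q.put(PersonRecord(slot_id="child", index=1, name="Akira",
                       sex=Sex.MALE, age=AgeValue.of(28),
                       general_status=["affected"], condition_key_refs=[1],
                       is_proband=True, is_consultand=True))
    q.put(PersonRecord(slot_id="child", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(25)))
    q.put(PersonRecord(slot_id="his_parents", index=1, sex=Sex.MALE,
                       general_status=["affected", "deceased"],
                       condition_key_refs=[1], age=AgeValue.of(78)))
    q.put(PersonRecord(slot_id="his_parents", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(80)))
    q.put(PersonRecord(slot_id="his_siblings", index=1, sex=Sex.FEMALE,
                       age=AgeValue.of(50), general_status=["affected"],
                       condition_key_refs=[1]))
    return q


def _scenario_ultimate() -> Questionnaire:
    q = Questionnaire(client_has_child=True, metadata=PedigreeMetadata(
        family_names="ultimate (synthetic)",
        paternal_ancestry="Tohoku", maternal_ancestry="Kansai",
        historian="intake clerk", reason_for_pedigree="feature exercise",
        date_of_intake=date(2017, 7, 14), remarks="fictitious family"))
    for slot, label in ((1, "cancer"), (2, "diabetes"),
                        (3, "heart disease"), (4, "stroke/brain attack")):
        q.key_table.entry(slot).label = label
        q.key_table.entry(slot).checked = True
    q.key_table.entry(2).show_below_symbol = True

    q.put(PersonRecord(slot_id="client", name="Jiro", sex=Sex.MALE,
                       age=AgeValue.of(35), is_consultand=True))
    q.put(PersonRecord(slot_id="spouse", name="Sachiko", sex=Sex.FEMALE,
                       age=AgeValue.of(34), general_status=["carrier"]))
    q.put(PersonRecord(slot_id="his_parents", index=1, sex=Sex.MALE,
                       age=AgeValue.of(70),
                       general_status=["affected", "deceased"],
                       condition_key_refs=[1]))
    q.put(PersonRecord(slot_id="his_parents", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(68),
                       general_status=["presymptomatic_carrier"]))
    q.put(PersonRecord(slot_id="his_siblings", index=1, sex=Sex.FEMALE,
                       age=AgeValue.of(40), general_status=["affected"],
                       condition_key_refs=[1, 2], remarks="E+"))
    q.put(PersonRecord(slot_id="his_siblings", index=2, sex=Sex.MALE,
                       age=AgeValue.of(38), adoption="adopted_out"))
    q.put(PersonRecord(slot_id="his_siblings", index=3, sex=Sex.MALE,
                       age=AgeValue.of(37), infertility=True))
    q.put(PersonRecord(slot_id="his_siblings", index=4, sex=Sex.FEMALE,
                       age=AgeValue.of(33), no_children_by_choice=True))
    q.put(PersonRecord(slot_id="his_siblings", index=5, sex=Sex.MALE,
                       history_unknown=True))
    q.put(PersonRecord(slot_id="his_siblings", index=6, sex=Sex.MALE,
                       multiple_individuals=5))
    q.put(PersonRecord(slot_id="his_siblings", index=7, sex=Sex.FEMALE,
                       multiple_individuals=N_UNKNOWN))
    q.put(PersonRecord(slot_id="his_paternal_uncles_aunts", index=1,
                       sex=Sex.MALE, age=AgeValue.unknown(), remarks="Eu"))
    q.put(PersonRecord(slot_id="his_divorced_partners", index=1,
                       name="Mariko", sex=Sex.FEMALE, age=AgeValue.of(36)))
    q.put(PersonRecord(slot_id="her_parents", index=1, sex=Sex.MALE,
                       age=AgeValue.of(66)))
    q.put(PersonRecord(slot_id="her_parents", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(64)))
    q.put(PersonRecord(slot_id="her_siblings", index=1, sex=Sex.FEMALE,
                       age=AgeValue.of(30), donor_surrogate="donor"))
    q.put(PersonRecord(slot_id="her_siblings", index=2, sex=Sex.FEMALE,
                       age=AgeValue.of(28), donor_surrogate="surrogate"))
    q.put(PersonRecord(slot_id="her_siblings", index=3, sex=Sex.MALE,
                       age=AgeValue.of(26), multiple_gestation_id=7))
    q.put(PersonRecord(slot_id="her_siblings", index=4, sex=Sex.FEMALE,
                       age=AgeValue.of(26), multiple_gestation_id=7))

    # children: ex-partner's child, monozygotic twins, a pregnancy and the
    # full range of pregnancy outcomes, an adopted-in child, the proband
    q.put(PersonRecord(slot_id="child", index=1, sex=Sex.FEMALE,
                       age=AgeValue.of(12), of_divorced_partner=1,
                       divorced_side="his", custody_flag=True))
    q.put(PersonRecord(slot_id="child", index=2, sex=Sex.MALE,
                       age=AgeValue.of(8), multiple_gestation_id=1,
                       monozygotic=True))
    q.put(PersonRecord(slot_id="child", index=3, sex=Sex.MALE,
                       age=AgeValue.of(8), multiple_gestation_id=1,
                       monozygotic=True))
    q.put(PersonRecord(slot_id="child", index=4, sex=Sex.MALE,
                       age=AgeValue.of(5), general_status=["affected"],
                       condition_key_refs=[3, 4], is_proband=True,
                       show_below="follow-up"))
    q.put(PersonRecord(slot_id="child", index=5, sex=Sex.FEMALE,
                       age=AgeValue.of(3), adoption="adopted_in"))
    q.put(PersonRecord(slot_id="child", index=6, pregnancy=True,
                       gestational_age=GestationalAge.of(12)))
    q.put(PersonRecord(slot_id="child", index=7, fetal_status="affected_SAB",
                       condition_key_refs=[2],
                       gestational_age=GestationalAge.of(9)))
    q.put(PersonRecord(slot_id="child", index=8, fetal_status="TOP",
                       gestational_age=GestationalAge.of(14)))
    q.put(PersonRecord(slot_id="child", index=9, sex=Sex.FEMALE,
                       fetal_status="stillbirth",
                       gestational_age=GestationalAge.of(33)))
    return q


def scenario_questionnaire(name: str) -> Questionnaire:
    """Deterministic questionnaire for a named verification scenario."""
    try:
        return {
            "D": _scenario_d,
            "P": _scenario_p,
            "VHL": _scenario_vhl,
            "ultimate": _scenario_ultimate,
            "minimal": lambda: blank_questionnaire(False),
        }[name]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {SCENARIOS}") from None


# ---------------------------------------------------------------------------
# randomized questionnaires


_GIVEN = ("Aoi", "Ren", "Hina", "Sota", "Yui", "Riku", "Mei", "Kaito",
          "Saki", "Hiro")


def random_questionnaire(seed: int, slot_fill: float = 0.5,
                         affected_rate: float = 0.15, twin_rate: float = 0.1,
                         consanguinity_rate: float = 0.05) -> Questionnaire:
    """A schema-valid random questionnaire; deterministic for a fixed seed.

    ``slot_fill`` drives how many optional slots are entered, ``affected_rate``
    the per-person probability of affected status, ``twin_rate`` the
    probability that the children row contains a twin pair, and
    ``consanguinity_rate`` the probability of a first-cousin overlay marriage.
    """
    for name, v in (("slot_fill", slot_fill), ("affected_rate", affected_rate),
                    ("twin_rate", twin_rate),
                    ("consanguinity_rate", consanguinity_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = random.Random(seed)
    has = rng.random() < 0.5
    q = Questionnaire(client_has_child=has, metadata=PedigreeMetadata(
        family_names=f"random family {seed}"))
    for slot in range(1, 5):
        q.key_table.entry(slot).label = f"condition {slot}"
        q.key_table.entry(slot).checked = rng.random() < 0.5

    def age(lo: int, hi: int) -> AgeValue:
        r = rng.random()
        if r < 0.1:
            return AgeValue.blank()
        if r < 0.2:
            return AgeValue.unknown()
        return AgeValue.of(rng.randint(lo, hi))

    def decorate(rec: PersonRecord, *, can_die: bool = True,
                 can_carry: bool = True) -> PersonRecord:
        if rng.random() < affected_rate:
            rec.general_status.append("affected")
            rec.condition_key_refs = sorted(rng.sample(
                range(1, 5), k=rng.choice((1, 1, 1, 2))))
        elif can_carry and rng.random() < 0.1:
            rec.general_status.append(
                rng.choice(("carrier", "presymptomatic_carrier")))
        if can_die and rng.random() < 0.12:
            rec.general_status.append("deceased")
        if rng.random() < 0.3:
            rec.name = rng.choice(_GIVEN)
        return rec

    consang = rng.random() < consanguinity_rate

    q.put(decorate(PersonRecord(slot_id="client", sex=Sex.MALE,
                                age=age(25, 50)), can_die=False))
    if consang:
        # wife entered minimally here and fully as an uncle's daughter
        q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE,
                           is_consultand=True, consanguinity_flag=True,
                           overlay_id=1))
        q.put(PersonRecord(slot_id="his_parents", index=1, sex=Sex.MALE,
                           age=age(50, 80)))
        q.put(PersonRecord(slot_id="his_parents", index=2, sex=Sex.FEMALE,
                           age=age(50, 80)))
        q.put(PersonRecord(slot_id="his_paternal_uncles_aunts", index=1,
                           sex=Sex.MALE, age=age(50, 80)))
        q.put(decorate(PersonRecord(slot_id="his_paternal_cousins", index=1,
                                    parent_index=1, sex=Sex.FEMALE,
                                    age=age(25, 50), consanguinity_flag=True,
                                    overlay_id=1), can_die=False))
    else:
        q.put(decorate(PersonRecord(slot_id="spouse", sex=Sex.FEMALE,
                                    age=age(25, 50), is_consultand=True),
                       can_die=False))
        if rng.random() < slot_fill:
            for idx, sex in ((1, Sex.MALE), (2, Sex.FEMALE)):
                q.put(decorate(PersonRecord(slot_id="his_parents", index=idx,
                                            sex=sex, age=age(50, 85))))
        if rng.random() < slot_fill * 0.6:
            for k in range(1, rng.randint(2, 4)):
                q.put(decorate(PersonRecord(
                    slot_id="his_paternal_uncles_aunts", index=k,
                    sex=rng.choice((Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)),
                    age=age(50, 85))))
        if rng.random() < slot_fill:
            for idx, sex in ((1, Sex.MALE), (2, Sex.FEMALE)):
                q.put(decorate(PersonRecord(slot_id="her_parents", index=idx,
                                            sex=sex, age=age(50, 85))))
        for side in ("his", "her"):
            if rng.random() < slot_fill:
                for k in range(1, rng.randint(1, 4) + 1):
                    rec = decorate(PersonRecord(
                        slot_id=f"{side}_siblings", index=k,
                        sex=rng.choice((Sex.MALE, Sex.FEMALE)),
                        age=age(20, 60)))
                    if rng.random() < 0.08:
                        rec.infertility = True
                    q.put(rec)

    # children row: under the no-child branch index 1 is the client
    n_children = rng.randint(1, 5) if has else rng.randint(1, 3)
    twin_pair = rng.random() < twin_rate and n_children >= 2
    twin_at = rng.randint(1, n_children - 1) if twin_pair else 0
    proband_at = rng.randint(1, n_children)
    twin_sex = rng.choice((Sex.MALE, Sex.FEMALE))
    mono = rng.random() < 0.5
    for k in range(1, n_children + 1):
        in_twin = twin_pair and k in (twin_at, twin_at + 1)
        rec = PersonRecord(
            slot_id="child", index=k,
            sex=(twin_sex if in_twin and mono
                 else rng.choice((Sex.MALE, Sex.FEMALE, Sex.UNKNOWN))),
            age=age(0, 30))
        if in_twin:
            rec.multiple_gestation_id = 1
            rec.monozygotic = mono
        decorate(rec, can_die=not in_twin)
        if not has and k == 1:
            rec.is_consultand = True
        if k == proband_at and not in_twin:
            rec.is_proband = True
        elif (not in_twin and not rec.is_consultand and
              rng.random() < 0.05):
            rec.multiple_individuals = rng.choice((2, 3, N_UNKNOWN))
        if (rec.multiple_individuals == 1 and not in_twin and
                "deceased" not in rec.general_status and
                not rec.is_proband and not rec.is_consultand and
                rng.random() < 0.08):
            rec.pregnancy = True
            rec.gestational_age = GestationalAge.of(rng.randint(4, 40))
        q.put(rec)
    return q


# ---------------------------------------------------------------------------
# concordance scoring


@dataclass
class ConcordanceScore:
    matched_elements: int
    total_elements: int
    fraction: float
    element_breakdown: dict[str, tuple[int, int]] = field(default_factory=dict)


def _elements(p: Pedigree) -> dict:
    """Position-keyed structural elements: ids never enter the keys, so the
    score is invariant to individual-id relabeling."""
    orders = generation_orders(p)
    levels = occupied_levels(p)
    pos: dict[str, tuple[int, int]] = {}
    for g, ids in orders.items():
        for n, iid in enumerate(ids):
            pos[iid] = (levels.index(g), n)
    els: dict = {}
    for iid, ind in p.individuals.items():
        at = pos[iid]
        els[("individual", at)] = True
        els[("sex", at)] = ind.sex.value
        els[("life_stage", at)] = ind.life_stage.value
        els[("affected", at)] = (ind.affected, tuple(sorted(ind.condition_keys)))
        els[("carrier", at)] = (ind.carrier, ind.presymptomatic_carrier)
        els[("marks", at)] = (ind.is_proband, ind.is_consultand)
        els[("multiple", at)] = str(ind.multiple_count)
    for u in p.unions.values():
        key = ("union",) + tuple(sorted((pos[u.partner_a], pos[u.partner_b])))
        els[key] = (u.status.value, u.consanguineous)
    for s in p.sibships.values():
        kids = tuple(sorted(pos[c] for c in s.children))
        if s.union_id is not None:
            u = p.unions[s.union_id]
            anchor = tuple(sorted((pos[u.partner_a], pos[u.partner_b])))
        else:
            anchor = ("free",)
        els[("sibship",) + anchor] = kids
        for tg in s.twin_groups:
            els[("twins", tuple(sorted(pos[m] for m in tg.members)))] = \
                tg.zygosity.value
    return els


_CATEGORIES = ("individual", "sex", "life_stage", "affected", "carrier",
               "marks", "multiple", "union", "sibship", "twins")


def score_concordance(candidate: Pedigree,
                      reference: Pedigree) -> ConcordanceScore:
    """Element-match score between two pedigrees.

    Individuals are aligned by generation rank and left-to-right position;
    every aligned element (existence, sex, status, marks, unions, sibships,
    twin groups) is worth one point.  The fraction is matched elements over
    the union of both element sets, so extra and missing structure both cost;
    it is 1.0 exactly when the pedigrees are attribute-identical up to id
    relabeling.
    """
    a, b = _elements(candidate), _elements(reference)
    keys = set(a) | set(b)
    matched = sum(1 for k in keys if k in a and k in b and a[k] == b[k])
    total = len(keys)
    breakdown = {}
    for cat in _CATEGORIES:
        ck = [k for k in keys if k[0] == cat]
        cm = sum(1 for k in ck if k in a and k in b and a[k] == b[k])
        if ck:
            breakdown[cat] = (cm, len(ck))
    return ConcordanceScore(
        matched_elements=matched,
        total_elements=total,
        fraction=(matched / total) if total else 1.0,
        element_breakdown=breakdown,
    )
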