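"""Build a validated pedigree graph from a questionnaire.

Slot placement: with a child, the central couple (generation 2) is the client
couple and the bottom row holds their children; without a child the central
couple is the client's parents and the client sits in the bottom row.  Either
way parents of the central couple occupy generation 1, and uncles/aunts hang
from a free sibling line next to their sibling parent (their own parents fall
outside the three-generation frame).

Blank-slot materialization: a connecting relative (a parent pair, an
uncle/aunt named by a cousin record, a spouse of an individual with an
infertile union) is created as a sex-typed, unnamed, history-unknown
individual only when a filled slot requires it to connect entered
individuals.

The consanguinity overlay fuses two records that describe the same person
from two family vantage points (typically the spouse entered minimally on the
client branch and fully as an uncle's child), producing the first-cousin
marriage loop drawn with a double relationship line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .layout import generation_orders
from .model import (
    Adoption,
    Comment,
    Custody,
    GameteRole,
    Individual,
    LifeStage,
    Pedigree,
    Sex,
    Sibship,
    TwinGroup,
    Union,
    UnionStatus,
    Zygosity,
    roman_label,
)
from .questionnaire import (
    PersonRecord,
    Questionnaire,
    relationship_slots,
    slot_def,
    validate_questionnaire,
)


class BuildError(ValueError):
    """Contradictory questionnaire records; lists the offending slots."""

    def __init__(self, message: str, slots: Optional[list[str]] = None) -> None:
        self.slots = slots or []
        if self.slots:
            message = f"{message} (slots: {', '.join(self.slots)})"
        super().__init__(message)


class OverlayError(ValueError):
    """An overlay group cannot be fused."""


class OverlayWarning(UserWarning):
    """The fused spouses are not first cousins (a capability note)."""


class PedigreeCommentError(KeyError):
    pass


@dataclass(frozen=True)
class OverlayGroup:
    overlay_id: int
    member_ids: tuple[str, str]  # individual ids after the raw build


_FETAL_STAGE = {
    "SAB": LifeStage.SAB,
    "affected_SAB": LifeStage.SAB,
    "TOP": LifeStage.TOP,
    "affected_TOP": LifeStage.TOP,
    "stillbirth": LifeStage.STILLBIRTH,
    "ectopic": LifeStage.ECTOPIC,
}
_AUTO_ANNOTATION = {LifeStage.STILLBIRTH: "SB", LifeStage.ECTOPIC: "ECT"}
_NO_CHILDREN_STAGES = frozenset(
    {LifeStage.PREGNANCY, LifeStage.SAB, LifeStage.TOP, LifeStage.STILLBIRTH,
     LifeStage.ECTOPIC})

#: slots whose occupants are parents in the chart; pregnancy/fetal status on
#: them is contradictory
_PARENT_SLOTS = {"client", "spouse", "his_parents", "her_parents"}


class _Build:
    def __init__(self, q: Questionnaire) -> None:
        self.q = q
        self.has = q.client_has_child
        self.p = Pedigree(metadata=q.metadata, key_table=q.key_table)
        self.ids: dict[tuple[str, int], str] = {}  # (slot, index) -> ind id
        self._n = {"i": 0, "u": 0, "s": 0}
        # left-to-right row sections, assembled into order keys at the end
        self.g1: list[str] = []
        self.g2_his: list[str] = []
        self.g2_center: list[str] = []
        self.g2_her: list[str] = []
        self.g3_pre: list[str] = []
        self.g3_mid: list[str] = []
        self.g3_post: list[str] = []
        self._g2 = self.g2_his
        self._g3 = self.g3_mid

    # -- id helpers -------------------------------------------------------

    def _next(self, prefix: str) -> str:
        self._n[prefix] += 1
        return f"{prefix}{self._n[prefix]}"

    def _nonblank(self, slot_id: str, index: int) -> Optional[PersonRecord]:
        r = self.q.record(slot_id, index)
        if r is not None and not r.is_blank(self.has):
            return r
        return None

    def _filled(self, slot_id: str) -> list[PersonRecord]:
        return [r for r in self.q.records.get(slot_id, [])
                if not r.is_blank(self.has)]

    def _row_for(self, generation: int) -> list[str]:
        return {1: self.g1, 2: self._g2, 3: self._g3}[generation]

    # -- individual construction -----------------------------------------

    def _default_sex(self, slot_id: str, index: int) -> Sex:
        sexes = slot_def(slot_id).default_sexes
        return sexes[min(index, len(sexes)) - 1]

    def _from_record(self, r: PersonRecord, generation: int) -> Individual:
        where = f"{r.slot_id}[{r.index}]"
        gs = set(r.general_status)
        ind = Individual(id=self._next("i"), generation=generation)
        ind.sex = r.sex if r.sex is not None else self._default_sex(
            r.slot_id, r.index)
        ind.name = r.effective_name(self.has)
        ind.age = r.age
        ind.gestational_age = r.gestational_age

        if r.pregnancy and r.fetal_status != "none":
            raise BuildError("pregnancy and a fetal outcome are contradictory",
                             [where])
        if "deceased" in gs and (r.pregnancy or r.fetal_status != "none"):
            raise BuildError("pregnancy status on a deceased individual",
                             [where])
        if (r.pregnancy or r.fetal_status != "none") and \
                r.slot_id in _PARENT_SLOTS:
            raise BuildError("pregnancy/fetal status on a parent slot", [where])
        if r.pregnancy:
            ind.life_stage = LifeStage.PREGNANCY
        elif r.fetal_status != "none":
            ind.life_stage = _FETAL_STAGE[r.fetal_status]
        elif "deceased" in gs:
            ind.life_stage = LifeStage.DECEASED

        affected = "affected" in gs or r.fetal_status.startswith("affected") \
            or bool(r.condition_key_refs)
        if affected:
            ind.affected = True
            # an affected record without checked keys fills with the base key
            ind.condition_keys = sorted(set(r.condition_key_refs)) or [1]
        if "carrier" in gs and "presymptomatic_carrier" in gs:
            raise BuildError("carrier and presymptomatic carrier are mutually "
                             "exclusive", [where])
        ind.carrier = "carrier" in gs
        ind.presymptomatic_carrier = "presymptomatic_carrier" in gs

        ind.multiple_count = r.multiple_individuals
        if ind.multiple_count != 1 and (r.is_proband or r.is_consultand or
                                        r.pregnancy):
            raise BuildError("a multiple-individuals node cannot be proband, "
                             "consultand or a pregnancy", [where])
        ind.adoption = r.adoption
        ind.gamete_role = r.donor_surrogate
        ind.history_unknown = r.history_unknown
        ind.show_below = r.show_below
        if r.remarks:
            ind.annotations.append(r.remarks)
        auto = _AUTO_ANNOTATION.get(ind.life_stage)
        if auto:
            ind.annotations.append(auto)

        ind.is_proband = r.is_proband
        ind.is_consultand = r.is_consultand
        if r.is_proband:
            self.p.proband_id = ind.id
        if r.is_consultand:
            self.p.consultand_ids.append(ind.id)
        self.p.add(ind)
        self.ids[(r.slot_id, r.index)] = ind.id
        return ind

    def _connector(self, sex: Sex, generation: int,
                   slot_key: Optional[tuple[str, int]] = None) -> Individual:
        ind = Individual(id=self._next("i"), sex=sex, generation=generation,
                         history_unknown=True)
        self.p.add(ind)
        if slot_key:
            self.ids[slot_key] = ind.id
        return ind

    def _slot_individual(self, slot_id: str, index: int, generation: int,
                         required: bool = False,
                         materialize_blank: bool = False) -> Optional[Individual]:
        """Materialize one slot record: entered data, a plain individual from
        the blank record (mandatory client nodes), or a connector when the
        slot is structurally required but left blank."""
        key = (slot_id, index)
        if key in self.ids:
            return self.p.individuals[self.ids[key]]
        r = self._nonblank(slot_id, index)
        if r is not None:
            return self._from_record(r, generation)
        if materialize_blank:
            blank = self.q.record(slot_id, index) or PersonRecord(
                slot_id=slot_id, index=index)
            return self._from_record(blank, generation)
        if required:
            return self._connector(self._default_sex(slot_id, index),
                                   generation, key)
        return None

    def _union(self, a: Individual, b: Individual, **kw) -> Union:
        u = Union(id=self._next("u"), partner_a=a.id, partner_b=b.id, **kw)
        self.p.add(u)
        return u

    def _sibship(self, union: Optional[Union],
                 children: list[Individual]) -> Sibship:
        s = Sibship(id=self._next("s"),
                    union_id=union.id if union else None,
                    children=[c.id for c in children])
        self.p.add(s)
        return s

    # -- per-union flags (infertility / no children by choice) ------------

    def _childless_flags(self, recs: list[PersonRecord]) -> dict[str, bool]:
        return {
            "infertility": any(r.infertility for r in recs),
            "no_children_by_choice": any(r.no_children_by_choice for r in recs),
        }

    def _partnerless_flags(self, ind: Individual, r: PersonRecord) -> None:
        """A non-central record flagged infertile/childless gets a connector
        partner so the union marker has a line to hang from."""
        if not (r.infertility or r.no_children_by_choice):
            return
        partner = self._connector(Sex.UNKNOWN, ind.generation)
        self._union(ind, partner, **self._childless_flags([r]))
        self._row_for(ind.generation).append(partner.id)

    # -- twin grouping ----------------------------------------------------

    def _twin_groups(self, recs: list[PersonRecord],
                     inds: dict[int, Individual]
                     ) -> tuple[list[int], list[TwinGroup]]:
        """Order children eldest-first with gestation groups consecutive and
        derive twin groups; returns (ordered record indexes, twin groups)."""
        by_gid: dict[int, list[PersonRecord]] = {}
        for r in recs:
            if r.multiple_gestation_id is not None:
                by_gid.setdefault(r.multiple_gestation_id, []).append(r)
        grouped = {gid for gid, ms in by_gid.items() if len(ms) > 1}
        order = sorted(
            recs,
            key=lambda r: (min(x.index for x in by_gid[r.multiple_gestation_id])
                           if r.multiple_gestation_id in grouped else r.index,
                           r.index))
        groups: list[TwinGroup] = []
        for gid in sorted(grouped):
            members = by_gid[gid]
            mono = any(m.monozygotic for m in members)
            sexes = {inds[m.index].sex for m in members} - {Sex.UNKNOWN}
            if mono and len(sexes) > 1:
                raise BuildError(
                    "monozygotic twins cannot have different sexes",
                    [f"{m.slot_id}[{m.index}]" for m in members])
            if mono:
                if len(sexes) == 1:  # harmonize members left sex-unknown
                    for m in members:
                        inds[m.index].sex = next(iter(sexes))
                zyg = Zygosity.MONOZYGOTIC
            elif len(members) == 2:
                zyg = Zygosity.DIZYGOTIC
            elif len(members) == 3:
                zyg = Zygosity.TRIZYGOTIC
            else:
                zyg = Zygosity.UNKNOWN
                for m in members:
                    inds[m.index].annotations.append("zygosity ?")
            groups.append(TwinGroup(members=[inds[m.index].id for m in members],
                                    zygosity=zyg))
        return [r.index for r in order], groups

    def _build_children(self, union: Optional[Union],
                        recs: list[PersonRecord], target: list[str]
                        ) -> dict[int, Individual]:
        inds: dict[int, Individual] = {}
        for r in sorted(recs, key=lambda r: r.index):
            inds[r.index] = self._from_record(r, 3)
        order, twins = self._twin_groups(recs, inds)
        if union is not None:
            sib = self._sibship(union, [inds[i] for i in order])
            sib.twin_groups = twins
        for i in order:
            target.append(inds[i].id)
            r = next(r for r in recs if r.index == i)
            self._g3 = target
            self._partnerless_flags(inds[i], r)
        return inds

    # -- sides ------------------------------------------------------------

    def _uncle_family(self, side: str, branch: str,
                      sibling_parent: Individual) -> None:
        """One uncle/aunt slot family plus its cousin children; uncles share a
        free sibling line with ``sibling_parent``."""
        ua_slot = f"{side}_{branch}_uncles_aunts"
        cz_slot = f"{side}_{branch}_cousins"
        cousin_by_parent: dict[int, list[PersonRecord]] = {}
        for r in self._filled(cz_slot):
            cousin_by_parent.setdefault(r.parent_index, []).append(r)
        indexes = sorted({r.index for r in self._filled(ua_slot)} |
                         set(cousin_by_parent))
        if not indexes:
            return
        uncles: list[Individual] = []
        for idx in indexes:
            u = self._slot_individual(ua_slot, idx, 1, required=True)
            uncles.append(u)
            self.g1.append(u.id)
            rec = self.q.record(ua_slot, idx)
            kids = cousin_by_parent.get(idx, [])
            if kids:
                if u.life_stage in _NO_CHILDREN_STAGES:
                    raise BuildError("a pregnancy/loss node cannot have "
                                     "children", [f"{ua_slot}[{idx}]"])
                spouse = self._connector(Sex.UNKNOWN, 1)
                self.g1.append(spouse.id)
                union = self._union(u, spouse)
                cousins: dict[int, Individual] = {}
                for kr in sorted(kids, key=lambda r: r.index):
                    cousins[kr.index] = self._from_record(kr, 2)
                order, twins = self._twin_groups(kids, cousins)
                sib = self._sibship(union, [cousins[i] for i in order])
                sib.twin_groups = twins
                for i in order:
                    self._g2.append(cousins[i].id)
                    kr = next(r for r in kids if r.index == i)
                    self._partnerless_flags(cousins[i], kr)
            elif rec is not None:
                self._partnerless_flags(u, rec)
        # free sibling line connecting the uncles/aunts to the central parent
        if branch == "paternal":
            members = uncles + [sibling_parent]
        else:
            members = [sibling_parent] + uncles
        self._sibship(None, members)

    def _side(self, side: str, central: Individual) -> None:
        """Parents, siblings, uncles/aunts and cousins of one central-couple
        member."""
        self._g2 = self.g2_his if side == "his" else self.g2_her
        par_slot = f"{side}_parents"
        sib_slot = f"{side}_siblings"
        need_parents = bool(
            self._filled(par_slot) or self._filled(sib_slot) or
            self._filled(f"{side}_paternal_uncles_aunts") or
            self._filled(f"{side}_maternal_uncles_aunts") or
            self._filled(f"{side}_paternal_cousins") or
            self._filled(f"{side}_maternal_cousins"))
        if not need_parents:
            return
        father = self._slot_individual(par_slot, 1, 1, required=True)
        mother = self._slot_individual(par_slot, 2, 1, required=True)
        union = self._union(father, mother)

        sib_recs = self._filled(sib_slot)
        sib_inds: dict[int, Individual] = {}
        for r in sorted(sib_recs, key=lambda r: r.index):
            sib_inds[r.index] = self._from_record(r, 2)
        order, twins = self._twin_groups(sib_recs, sib_inds)
        ordered = [sib_inds[i] for i in order]
        # the central member sits nearest their spouse among the siblings
        children = ordered + [central] if side == "his" else [central] + ordered
        sib = self._sibship(union, children)
        sib.twin_groups = twins
        for i in order:
            self._g2.append(sib_inds[i].id)
            r = next(x for x in sib_recs if x.index == i)
            self._partnerless_flags(sib_inds[i], r)

        self._uncle_family(side, "paternal", father)
        self.g1.extend([father.id, mother.id])
        self._uncle_family(side, "maternal", mother)

    def _divorced_partner(self, side: str, central: Individual,
                          needed: bool) -> Optional[tuple[Union, Individual]]:
        slot = f"{side}_divorced_partners"
        recs = self._filled(slot)
        if not recs and not needed:
            return None
        if len(recs) > 1:
            raise BuildError(
                "at most one divorced partner per central-couple member can "
                "be drawn (relationship lines must stay adjacent)",
                [f"{slot}[{r.index}]" for r in recs])
        idx = recs[0].index if recs else 1
        dp = self._slot_individual(slot, idx, 2, required=True)
        return self._union(central, dp, status=UnionStatus.DIVORCED), dp

    # -- main -------------------------------------------------------------

    def run(self) -> Pedigree:
        q, has = self.q, self.has
        child_recs = self._filled("child")
        central_kid_recs = [r for r in child_recs
                            if r.of_divorced_partner is None]
        dp_kid_recs: dict[str, list[PersonRecord]] = {"his": [], "her": []}
        for r in child_recs:
            if r.of_divorced_partner is not None:
                dp_kid_recs[r.divorced_side].append(r)

        # the client node is mandatory under the no-child branch
        if not has and not any(r.index == 1 for r in child_recs):
            central_kid_recs.append(
                q.record("child", 1) or PersonRecord(slot_id="child", index=1))

        side_filled = any(
            self._filled(s.slot_id) for s in relationship_slots(has)
            if s.slot_id.startswith(("his_", "her_")))
        need_central = bool(
            has or self._nonblank("client", 1) or self._nonblank("spouse", 1)
            or len(central_kid_recs) > 1 or any(dp_kid_recs.values())
            or side_filled)

        husband = wife = None
        central_union = None
        if need_central:
            husband = self._slot_individual("client", 1, 2,
                                            materialize_blank=True)
            wife = self._slot_individual("spouse", 1, 2,
                                         materialize_blank=True)
            recs = [r for r in (q.record("client", 1), q.record("spouse", 1))
                    if r]
            flags = self._childless_flags(recs)
            consang = any(r.consanguinity_flag and r.overlay_id is None
                          for r in recs)
            central_union = self._union(husband, wife, consanguineous=consang,
                                        **flags)
            if any(flags.values()) and central_kid_recs:
                raise BuildError("central union flagged childless but has "
                                 "children", ["client", "spouse", "child"])

        if central_kid_recs:
            self._build_children(central_union, central_kid_recs, self.g3_mid)

        dp_ids: dict[str, Optional[str]] = {"his": None, "her": None}
        if husband is not None:
            self._side("his", husband)
            res = self._divorced_partner("his", husband,
                                         bool(dp_kid_recs["his"]))
            if res:
                union, dp = res
                dp_ids["his"] = dp.id
                self._dp_children(union, dp_kid_recs["his"], husband,
                                  self.g3_pre)
        if wife is not None:
            self._side("her", wife)
            res = self._divorced_partner("her", wife,
                                         bool(dp_kid_recs["her"]))
            if res:
                union, dp = res
                dp_ids["her"] = dp.id
                self._dp_children(union, dp_kid_recs["her"], wife,
                                  self.g3_post)

        if dp_ids["his"]:
            self.g2_center.append(dp_ids["his"])
        if husband is not None:
            self.g2_center.extend([husband.id, wife.id])
        if dp_ids["her"]:
            self.g2_center.append(dp_ids["her"])

        self._assign_order()
        groups = self._overlay_groups()
        p = self.p
        if groups:
            p = apply_overlay(p, groups)
        return assign_identifiers(p)

    def _dp_children(self, union: Union, recs: list[PersonRecord],
                     central: Individual, target: list[str]) -> None:
        if not recs:
            return
        self._build_children(union, recs, target)
        if any(r.custody_flag for r in recs):
            # the custody box on a child marks the remaining central-couple
            # parent as holding primary responsibility
            union.custody = (Custody.PARTNER_A
                             if union.partner_a == central.id
                             else Custody.PARTNER_B)

    def _assign_order(self) -> None:
        rows = [
            self.g1,
            self.g2_his + self.g2_center + self.g2_her,
            self.g3_pre + self.g3_mid + self.g3_post,
        ]
        n = 1
        for row in rows:
            for iid in row:
                self.p.individuals[iid].order_key = n
                n += 1

    def _overlay_groups(self) -> list[OverlayGroup]:
        by_id: dict[int, list[str]] = {}
        for r in self.q.all_records():
            if r.overlay_id is None:
                continue
            key = (r.slot_id, r.index)
            if key not in self.ids:
                raise BuildError("overlay record did not materialize",
                                 [f"{r.slot_id}[{r.index}]"])
            by_id.setdefault(r.overlay_id, []).append(self.ids[key])
        groups = []
        for oid, members in sorted(by_id.items()):
            if len(members) != 2:
                raise BuildError(
                    f"Overlay ID {oid} must appear on exactly 2 records, "
                    f"found {len(members)}")
            groups.append(OverlayGroup(overlay_id=oid,
                                       member_ids=(members[0], members[1])))
        return groups


def build_pedigree(q: Questionnaire) -> Pedigree:
    """Transform a questionnaire into a validated pedigree.

    Non-blank records become individuals; unions and sibships follow the slot
    semantics; overlay groups are fused; generation/individual numbers are
    assigned.  Raises :class:`BuildError` on contradictory records.
    """
    validate_questionnaire(q)
    return _Build(q).run()


# ---------------------------------------------------------------------------
# identifiers


def assign_identifiers(p: Pedigree) -> Pedigree:
    """Label generations I/II/III top-down and number individuals 1..k left to
    right within each generation; deterministic for identical input."""
    for g, ids in sorted(generation_orders(p).items()):
        label = roman_label(p, g)
        for n, iid in enumerate(ids, start=1):
            p.individuals[iid].gen_label = label
            p.individuals[iid].number = n
    return p


# ---------------------------------------------------------------------------
# kinship helpers


def _sibling_set(p: Pedigree, iid: str) -> set[str]:
    s = p.sibship_of_child(iid)
    return set(s.children) if s else {iid}


def parent_couple(p: Pedigree, iid: str):
    """The parental couple of an individual: the union partners, a virtual
    couple implied by a parentless sibling line, or None for a founder."""
    s = p.sibship_of_child(iid)
    if s is None:
        return None
    if s.union_id is None:
        return ("virtual", s.id)
    return tuple(sorted(p.unions[s.union_id].partners))


def grandparent_couples(p: Pedigree, iid: str) -> set:
    """Parental couples of each parent (virtual couples included)."""
    out = set()
    s = p.sibship_of_child(iid)
    if s is None or s.union_id is None:
        return out
    for parent in p.unions[s.union_id].partners:
        c = parent_couple(p, parent)
        if c is not None:
            out.add(c)
    return out


def are_siblings(p: Pedigree, a: str, b: str) -> bool:
    return a != b and b in _sibling_set(p, a)


def are_first_cousins(p: Pedigree, a: str, b: str) -> bool:
    """True when a parent of each belongs to one sibling set (and the two are
    not themselves siblings)."""
    if a == b or are_siblings(p, a, b):
        return False
    for x in p.parents_of(a):
        for y in p.parents_of(b):
            if are_siblings(p, x, y):
                return True
    return False


# ---------------------------------------------------------------------------
# consanguinity overlay


def _merge_attr(a, b, default, what: str, ids):
    if a == default:
        return b
    if b == default or a == b:
        return a
    raise OverlayError(f"conflicting {what} on overlay pair {ids}: "
                       f"{a!r} vs {b!r}")


def apply_overlay(p: Pedigree, groups: list[OverlayGroup]) -> Pedigree:
    """Fuse each overlay pair into one individual and flag the consanguineous
    union.

    Attribute fusion: a blank/default value yields to the entered one; equal
    entered values must match exactly (the two records describe the same
    person seen from two vantage points).  Emits :class:`OverlayWarning` when
    the fused spouses are not first cousins — a capability note, since the
    overlay exists to draw first-cousin marriages."""
    for g in groups:
        a_id, b_id = g.member_ids
        if a_id not in p.individuals or b_id not in p.individuals:
            raise OverlayError(f"overlay {g.overlay_id}: unknown individual")
        a, b = p.individuals[a_id], p.individuals[b_id]
        ids = (a_id, b_id)
        if a.generation != b.generation:
            raise OverlayError(f"overlay {g.overlay_id}: members sit in "
                               "different generations")
        if p.sibship_of_child(a_id) and p.sibship_of_child(b_id):
            raise OverlayError(f"overlay {g.overlay_id}: both records carry "
                               "parents")

        a.sex = _merge_attr(a.sex, b.sex, Sex.UNKNOWN, "sex", ids)
        a.name = _merge_attr(a.name, b.name, "", "name", ids)
        if a.age.kind == "blank":
            a.age = b.age
        elif b.age.kind != "blank" and b.age != a.age:
            raise OverlayError(f"conflicting age on overlay pair {ids}")
        if a.life_stage == LifeStage.LIVING:
            a.life_stage = b.life_stage
        elif b.life_stage not in (LifeStage.LIVING, a.life_stage):
            raise OverlayError(f"conflicting life stage on overlay pair {ids}")
        a.condition_keys = sorted(set(a.condition_keys) | set(b.condition_keys))
        a.affected = a.affected or b.affected or bool(a.condition_keys)
        if a.affected and not a.condition_keys:
            a.condition_keys = [1]
        a.carrier = a.carrier or b.carrier
        a.presymptomatic_carrier = (a.presymptomatic_carrier or
                                    b.presymptomatic_carrier)
        if a.carrier and a.presymptomatic_carrier:
            raise OverlayError(
                f"conflicting carrier status on overlay pair {ids}")
        a.multiple_count = _merge_attr(a.multiple_count, b.multiple_count, 1,
                                       "multiple-individuals count", ids)
        a.adoption = _merge_attr(a.adoption, b.adoption, Adoption.NONE,
                                 "adoption", ids)
        a.gamete_role = _merge_attr(a.gamete_role, b.gamete_role,
                                    GameteRole.NONE, "donor/surrogate role",
                                    ids)
        a.is_proband = a.is_proband or b.is_proband
        a.is_consultand = a.is_consultand or b.is_consultand
        a.history_unknown = a.history_unknown and b.history_unknown
        a.annotations += [x for x in b.annotations if x not in a.annotations]
        a.show_below = _merge_attr(a.show_below, b.show_below, "",
                                   "show-below text", ids)
        a.order_key = min(a.order_key, b.order_key)

        # structural rewrite b -> a
        for u in p.unions.values():
            if u.partner_a == b_id:
                u.partner_a = a_id
            if u.partner_b == b_id:
                u.partner_b = a_id
            if u.partner_a == u.partner_b:
                raise OverlayError(
                    f"overlay {g.overlay_id} would fuse a union's partners")
        for s in p.sibships.values():
            s.children = [a_id if c == b_id else c for c in s.children]
            for tg in s.twin_groups:
                tg.members = [a_id if m == b_id else m for m in tg.members]
        if p.proband_id == b_id:
            p.proband_id = a_id
        p.consultand_ids = [a_id if c == b_id else c
                            for c in p.consultand_ids]
        for c in p.comments:
            if c.anchor == b_id:
                c.anchor = a_id
        del p.individuals[b_id]

        # mark the closed loop on the fused person's partnership(s)
        flagged = cousins = False
        for u in p.unions.values():
            if a_id not in u.partners:
                continue
            partner = u.partner_b if u.partner_a == a_id else u.partner_a
            if are_first_cousins(p, a_id, partner):
                u.consanguineous = True
                flagged = cousins = True
            elif grandparent_couples(p, a_id) & grandparent_couples(p, partner):
                u.consanguineous = True
                flagged = True
        if not flagged:
            for u in p.unions.values():
                if a_id in u.partners:
                    u.consanguineous = True
        if not cousins:
            warnings.warn(
                f"overlay {g.overlay_id}: fused spouses are not first "
                "cousins; the overlay is intended for first-cousin marriages",
                OverlayWarning, stacklevel=2)
    return p


# ---------------------------------------------------------------------------
# comments


def attach_comment(p: Pedigree, target, text: str) -> Pedigree:
    """Attach a free-text comment anchored to an individual id or a chart
    coordinate pair; comments survive serialization."""
    if isinstance(target, str):
        if target not in p.individuals:
            raise PedigreeCommentError(f"unknown comment target {target!r}")
        anchor = target
    else:
        x, y = target
        anchor = (float(x), float(y))
    n = max((int(c.id[1:]) for c in p.comments), default=0) + 1
    p.comments.append(Comment(id=f"c{n}", text=text, anchor=anchor))
    return p


def detach_comment(p: Pedigree, comment_id: str) -> Pedigree:
    before = len(p.comments)
    p.comments = [c for c in p.comments if c.id != comment_id]
    if len(p.comments) == before:
        raise PedigreeCommentError(f"unknown comment id {comment_id!r}")
    return p
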