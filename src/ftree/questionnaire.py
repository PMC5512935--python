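"""Branching family-history questionnaire: schema, file dialects, blank sheets.

At intake the client is first asked whether they have a child.  The answer
only relabels the fixed relationship-slot topology: with a child the central
couple is the client (consultand) couple and the bottom row holds their
children; without a child the central couple is the client's parents and the
client themself sits in the bottom row (third generation).  Either way the
sheet collects exactly three generations.

Two interchangeable file dialects are supported: a JSON document and a flat
CSV "interview sheet" (one row per person record, with ``meta`` and ``key``
section rows).  Both are versioned and round-trip losslessly; see
``docs/questionnaire_format.md`` for the field-by-field description.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, TextIO, Union as TUnion

from .model import (
    AgeValue,
    GestationalAge,
    KeyEntry,
    KeyTable,
    PedigreeMetadata,
    Sex,
    Adoption,
    GameteRole,
    N_UNKNOWN,
    KEY_TABLE_SIZE,
    CONDITION_KEY_CAP,
)

FORMAT_VERSION = "1.0"
#: maximum entries per repeated slot family (keeps the printed sheet bounded)
REPEAT_CAP = 9

FETAL_STATUSES = (
    "none", "SAB", "affected_SAB", "TOP", "affected_TOP", "stillbirth",
    "ectopic",
)

GENERAL_STATUSES = ("affected", "presymptomatic_carrier", "carrier", "deceased")


class QuestionnaireError(ValueError):
    """Schema violation in a questionnaire file; names the field and row."""


@dataclass(frozen=True)
class RelationshipSlot:
    slot_id: str
    cardinality: str  # single | couple | repeated
    label_with_child: str
    label_without_child: str
    generation: int
    #: default sexes of the slot members ((one per member for couple slots))
    default_sexes: tuple[Sex, ...] = (Sex.UNKNOWN,)

    def label(self, has_child: bool) -> str:
        return self.label_with_child if has_child else self.label_without_child

    def member_label(self, has_child: bool, index: int) -> str:
        """Default name for the index-th record of this slot (1-based)."""
        base = self.label(has_child)
        if self.cardinality == "couple":
            return f"{base} ({'father' if index == 1 else 'mother'})"
        if self.cardinality == "repeated":
            return f"{base} #{index}"
        return base


def _slots() -> tuple[RelationshipSlot, ...]:
    s = RelationshipSlot
    m, f, u = Sex.MALE, Sex.FEMALE, Sex.UNKNOWN
    return (
        # husband's (paternal) side
        s("his_parents", "couple", "Husband's (his) parents",
          "Paternal grandparents", 1, (m, f)),
        s("his_paternal_uncles_aunts", "repeated", "His paternal uncles/aunts",
          "Siblings of paternal grandfather", 1, (u,)),
        s("his_maternal_uncles_aunts", "repeated", "His maternal uncles/aunts",
          "Siblings of paternal grandmother", 1, (u,)),
        s("his_paternal_cousins", "repeated",
          "Children of his paternal uncles/aunts",
          "Children of siblings of paternal grandfather", 2, (u,)),
        s("his_maternal_cousins", "repeated",
          "Children of his maternal uncles/aunts",
          "Children of siblings of paternal grandmother", 2, (u,)),
        s("his_siblings", "repeated", "His siblings",
          "Paternal uncles/aunts", 2, (u,)),
        s("his_divorced_partners", "repeated", "His divorced partners",
          "Divorced partners of father", 2, (f,)),
        # central couple and the child row
        s("client", "single", "Client (consultand) couple (husband)",
          "Parents of client (father)", 2, (m,)),
        s("spouse", "single", "Client (consultand) couple (wife)",
          "Parents of client (mother)", 2, (f,)),
        s("child", "repeated", "Children of client couple",
          "Client (consultand)", 3, (u,)),
        # wife's (maternal) side
        s("her_parents", "couple", "Wife's (her) parents",
          "Maternal grandparents", 1, (m, f)),
        s("her_paternal_uncles_aunts", "repeated", "Her paternal uncles/aunts",
          "Siblings of maternal grandfather", 1, (u,)),
        s("her_maternal_uncles_aunts", "repeated", "Her maternal uncles/aunts",
          "Siblings of maternal grandmother", 1, (u,)),
        s("her_paternal_cousins", "repeated",
          "Children of her paternal uncles/aunts",
          "Children of siblings of maternal grandfather", 2, (u,)),
        s("her_maternal_cousins", "repeated",
          "Children of her maternal uncles/aunts",
          "Children of siblings of maternal grandmother", 2, (u,)),
        s("her_siblings", "repeated", "Her siblings",
          "Maternal uncles/aunts", 2, (u,)),
        s("her_divorced_partners", "repeated", "Her divorced partners",
          "Divorced partners of mother", 2, (m,)),
    )


_SLOT_ORDER = _slots()
_SLOT_BY_ID = {s.slot_id: s for s in _SLOT_ORDER}

#: cousin slot -> the uncle/aunt slot family holding their parent
COUSIN_PARENT_SLOT = {
    "his_paternal_cousins": "his_paternal_uncles_aunts",
    "his_maternal_cousins": "his_maternal_uncles_aunts",
    "her_paternal_cousins": "her_paternal_uncles_aunts",
    "her_maternal_cousins": "her_maternal_uncles_aunts",
}


def relationship_slots(has_child: bool) -> list[RelationshipSlot]:
    """The full ordered slot set; the branch only changes display labels.

    Order is deterministic: husband's side, central couple and children,
    then wife's side.
    """
    # labels are baked into the slot definitions; both branches share ids
    del has_child
    return list(_SLOT_ORDER)


def slot_def(slot_id: str) -> RelationshipSlot:
    try:
        return _SLOT_BY_ID[slot_id]
    except KeyError:
        raise QuestionnaireError(f"unknown relationship slot {slot_id!r}") from None


@dataclass
class PersonRecord:
    """One questionnaire entry: a relationship slot plus all per-person fields.

    A record left entirely at its defaults is "blank" and yields no
    individual.  The name field defaults to the relationship label and must
    be cleared before a real name is entered; a name equal to the default
    label is treated as unset.
    """

    slot_id: str
    index: int = 1
    name: str = ""
    age: AgeValue = field(default_factory=AgeValue.blank)
    sex: Optional[Sex] = None  # None -> slot default
    general_status: list[str] = field(default_factory=list)
    condition_key_refs: list[int] = field(default_factory=list)
    infertility: bool = False
    no_children_by_choice: bool = False
    pregnancy: bool = False
    fetal_status: str = "none"
    gestational_age: GestationalAge = field(default_factory=GestationalAge.blank)
    multiple_gestation_id: Optional[int] = None
    monozygotic: bool = False
    custody_flag: bool = False
    multiple_individuals: TUnion[int, str] = 1  # 1 | k>=2 | "n"
    adoption: Adoption = Adoption.NONE
    donor_surrogate: GameteRole = GameteRole.NONE
    consanguinity_flag: bool = False
    overlay_id: Optional[int] = None
    is_proband: bool = False
    is_consultand: bool = False
    history_unknown: bool = False
    parent_index: int = 1  # cousin slots: which uncle/aunt entry is the parent
    of_divorced_partner: Optional[int] = None  # child slots: ex-partner index
    divorced_side: str = ""  # "his" | "her" when of_divorced_partner is set
    show_below: str = ""
    remarks: str = ""

    def __post_init__(self) -> None:
        # accept plain strings for the enum-valued fields
        self.adoption = Adoption(self.adoption)
        self.donor_surrogate = GameteRole(self.donor_surrogate)
        if self.sex is not None:
            self.sex = Sex(self.sex)

    def default_name(self, has_child: bool) -> str:
        return slot_def(self.slot_id).member_label(has_child, self.index)

    def effective_name(self, has_child: bool) -> str:
        """The entered name, or "" when left at the relationship default."""
        if self.name and self.name != self.default_name(has_child):
            return self.name
        return ""

    def is_blank(self, has_child: bool) -> bool:
        ref = PersonRecord(slot_id=self.slot_id, index=self.index,
                           parent_index=self.parent_index)
        a = _record_to_json(self, has_child)
        b = _record_to_json(ref, has_child)
        a.pop("name"), b.pop("name")
        return a == b and self.effective_name(has_child) == ""


@dataclass
class Questionnaire:
    client_has_child: bool = True
    records: dict[str, list[PersonRecord]] = field(default_factory=dict)
    key_table: KeyTable = field(default_factory=KeyTable)
    metadata: PedigreeMetadata = field(default_factory=PedigreeMetadata)

    def record(self, slot_id: str, index: int = 1) -> Optional[PersonRecord]:
        for r in self.records.get(slot_id, []):
            if r.index == index:
                return r
        return None

    def put(self, rec: PersonRecord) -> PersonRecord:
        slot_def(rec.slot_id)  # raises on unknown slot
        lst = self.records.setdefault(rec.slot_id, [])
        lst[:] = [r for r in lst if r.index != rec.index]
        lst.append(rec)
        lst.sort(key=lambda r: r.index)
        return rec

    def all_records(self) -> list[PersonRecord]:
        out = []
        for slot in _SLOT_ORDER:
            out.extend(self.records.get(slot.slot_id, []))
        return out


def blank_questionnaire(has_child: bool) -> Questionnaire:
    """A fully populated default sheet: every slot holds a default record
    whose name is the relationship label, and the key table is 16 empty,
    unchecked entries."""
    q = Questionnaire(client_has_child=has_child)
    for slot in _SLOT_ORDER:
        n = 2 if slot.cardinality == "couple" else 1
        for i in range(1, n + 1):
            q.put(PersonRecord(slot_id=slot.slot_id, index=i,
                               name=slot.member_label(has_child, i)))
    return q


# ---------------------------------------------------------------------------
# validation


def validate_questionnaire(q: Questionnaire) -> None:
    """Raise :class:`QuestionnaireError` on any schema violation."""
    if len(q.key_table.entries) != KEY_TABLE_SIZE:
        raise QuestionnaireError(
            f"key_table: expected {KEY_TABLE_SIZE} entries, "
            f"got {len(q.key_table.entries)}")
    proband_count = 0
    for slot_id, recs in q.records.items():
        slot = slot_def(slot_id)
        cap = {"single": 1, "couple": 2, "repeated": REPEAT_CAP}[slot.cardinality]
        if len(recs) > cap:
            raise QuestionnaireError(
                f"{slot_id}: {len(recs)} records exceed the cap of {cap}")
        seen = set()
        for r in recs:
            where = f"{slot_id}[{r.index}]"
            if r.index < 1 or r.index > cap:
                raise QuestionnaireError(f"{where}: index out of range")
            if r.index in seen:
                raise QuestionnaireError(f"{where}: duplicate index")
            seen.add(r.index)
            if r.monozygotic and r.multiple_gestation_id is None:
                raise QuestionnaireError(
                    f"{where}: Monozygotic requires a Multiple-gestation ID")
            if r.overlay_id is not None and not r.consanguinity_flag:
                raise QuestionnaireError(
                    f"{where}: Overlay ID requires the Consanguinity box")
            if len(r.condition_key_refs) > CONDITION_KEY_CAP:
                raise QuestionnaireError(
                    f"{where}: more than {CONDITION_KEY_CAP} condition keys")
            if any(not 1 <= k <= CONDITION_KEY_CAP for k in r.condition_key_refs):
                raise QuestionnaireError(
                    f"{where}: condition keys must reference slots 1-4")
            for st in r.general_status:
                if st not in GENERAL_STATUSES:
                    raise QuestionnaireError(f"{where}: bad general status {st!r}")
            if r.fetal_status not in FETAL_STATUSES:
                raise QuestionnaireError(
                    f"{where}: bad fetal status {r.fetal_status!r}")
            if slot_id in COUSIN_PARENT_SLOT and not 1 <= r.parent_index <= REPEAT_CAP:
                raise QuestionnaireError(f"{where}: parent_index out of range")
            if r.of_divorced_partner is not None and r.divorced_side not in (
                    "his", "her"):
                raise QuestionnaireError(
                    f"{where}: of_divorced_partner requires divorced_side "
                    "'his' or 'her'")
            if r.is_proband:
                proband_count += 1
    if proband_count > 1:
        raise QuestionnaireError("more than one record flags the proband")


# ---------------------------------------------------------------------------
# JSON dialect

_REC_FIELDS = [
    "name", "age", "sex", "general_status", "condition_key_refs",
    "infertility", "no_children_by_choice", "pregnancy", "fetal_status",
    "gestational_age", "multiple_gestation_id", "monozygotic", "custody_flag",
    "multiple_individuals", "adoption", "donor_surrogate",
    "consanguinity_flag", "overlay_id", "is_proband", "is_consultand",
    "history_unknown", "parent_index", "of_divorced_partner", "divorced_side",
    "show_below", "remarks",
]


def _age_to_json(a: AgeValue):
    return {"blank": None, "unknown": "?"}.get(a.kind, a.years)


def _age_from_json(v, where: str) -> AgeValue:
    if v is None or v == "":
        return AgeValue.blank()
    if v == "?":
        return AgeValue.unknown()
    try:
        return AgeValue.of(int(v))
    except (TypeError, ValueError) as e:
        raise QuestionnaireError(f"{where}: bad age {v!r}: {e}") from None


def _gest_to_json(g: GestationalAge):
    return {"blank": None, "unknown": "?"}.get(g.kind, g.weeks)


def _gest_from_json(v, where: str) -> GestationalAge:
    if v is None or v == "":
        return GestationalAge.blank()
    if v == "?":
        return GestationalAge.unknown()
    try:
        return GestationalAge.of(int(v))
    except (TypeError, ValueError) as e:
        raise QuestionnaireError(f"{where}: bad gestational age {v!r}: {e}") from None


def _record_to_json(r: PersonRecord, has_child: bool) -> dict:
    return {
        "index": r.index,
        "name": r.name or r.default_name(has_child),
        "age": _age_to_json(r.age),
        "sex": r.sex.value if r.sex is not None else None,
        "general_status": list(r.general_status),
        "condition_key_refs": list(r.condition_key_refs),
        "infertility": r.infertility,
        "no_children_by_choice": r.no_children_by_choice,
        "pregnancy": r.pregnancy,
        "fetal_status": r.fetal_status,
        "gestational_age": _gest_to_json(r.gestational_age),
        "multiple_gestation_id": r.multiple_gestation_id,
        "monozygotic": r.monozygotic,
        "custody_flag": r.custody_flag,
        "multiple_individuals": r.multiple_individuals,
        "adoption": r.adoption.value,
        "donor_surrogate": r.donor_surrogate.value,
        "consanguinity_flag": r.consanguinity_flag,
        "overlay_id": r.overlay_id,
        "is_proband": r.is_proband,
        "is_consultand": r.is_consultand,
        "history_unknown": r.history_unknown,
        "parent_index": r.parent_index,
        "of_divorced_partner": r.of_divorced_partner,
        "divorced_side": r.divorced_side,
        "show_below": r.show_below,
        "remarks": r.remarks,
    }


def _record_from_json(slot_id: str, d: dict, where: str) -> PersonRecord:
    known = set(_REC_FIELDS) | {"index"}
    unknown = set(d) - known
    if unknown:
        raise QuestionnaireError(f"{where}: unknown fields {sorted(unknown)}")
    sex = d.get("sex")
    mi = d.get("multiple_individuals", 1)
    if mi != N_UNKNOWN:
        try:
            mi = int(mi)
        except (TypeError, ValueError):
            raise QuestionnaireError(
                f"{where}: bad multiple_individuals {mi!r}") from None
    try:
        return PersonRecord(
            slot_id=slot_id,
            index=int(d.get("index", 1)),
            name=str(d.get("name", "")),
            age=_age_from_json(d.get("age"), where),
            sex=Sex(sex) if sex is not None else None,
            general_status=list(d.get("general_status", [])),
            condition_key_refs=[int(k) for k in d.get("condition_key_refs", [])],
            infertility=bool(d.get("infertility", False)),
            no_children_by_choice=bool(d.get("no_children_by_choice", False)),
            pregnancy=bool(d.get("pregnancy", False)),
            fetal_status=str(d.get("fetal_status", "none")),
            gestational_age=_gest_from_json(d.get("gestational_age"), where),
            multiple_gestation_id=(None if d.get("multiple_gestation_id") is None
                                   else int(d["multiple_gestation_id"])),
            monozygotic=bool(d.get("monozygotic", False)),
            custody_flag=bool(d.get("custody_flag", False)),
            multiple_individuals=mi,
            adoption=Adoption(d.get("adoption", "none")),
            donor_surrogate=GameteRole(d.get("donor_surrogate", "none")),
            consanguinity_flag=bool(d.get("consanguinity_flag", False)),
            overlay_id=(None if d.get("overlay_id") is None
                        else int(d["overlay_id"])),
            is_proband=bool(d.get("is_proband", False)),
            is_consultand=bool(d.get("is_consultand", False)),
            history_unknown=bool(d.get("history_unknown", False)),
            parent_index=int(d.get("parent_index", 1)),
            of_divorced_partner=(None if d.get("of_divorced_partner") is None
                                 else int(d["of_divorced_partner"])),
            divorced_side=str(d.get("divorced_side", "")),
            show_below=str(d.get("show_below", "")),
            remarks=str(d.get("remarks", "")),
        )
    except ValueError as e:
        raise QuestionnaireError(f"{where}: {e}") from None


def _metadata_to_json(m: PedigreeMetadata) -> dict:
    return {
        "family_names": m.family_names,
        "paternal_ancestry": m.paternal_ancestry,
        "maternal_ancestry": m.maternal_ancestry,
        "date_of_intake": m.date_of_intake.isoformat() if m.date_of_intake else None,
        "historian": m.historian,
        "reason_for_pedigree": m.reason_for_pedigree,
        "remarks": m.remarks,
    }


def _metadata_from_json(d: dict, where: str = "metadata") -> PedigreeMetadata:
    known = {"family_names", "paternal_ancestry", "maternal_ancestry",
             "date_of_intake", "historian", "reason_for_pedigree", "remarks"}
    unknown = set(d) - known
    if unknown:
        raise QuestionnaireError(f"{where}: unknown fields {sorted(unknown)}")
    doi = d.get("date_of_intake")
    try:
        doi = date.fromisoformat(doi) if doi else None
    except ValueError as e:
        raise QuestionnaireError(f"{where}: bad date_of_intake: {e}") from None
    return PedigreeMetadata(
        family_names=str(d.get("family_names", "")),
        paternal_ancestry=str(d.get("paternal_ancestry", "")),
        maternal_ancestry=str(d.get("maternal_ancestry", "")),
        date_of_intake=doi,
        historian=str(d.get("historian", "")),
        reason_for_pedigree=str(d.get("reason_for_pedigree", "")),
        remarks=str(d.get("remarks", "")),
    )


def questionnaire_to_json(q: Questionnaire) -> dict:
    validate_questionnaire(q)
    records = {}
    for slot in _SLOT_ORDER:
        recs = q.records.get(slot.slot_id, [])
        if recs:
            records[slot.slot_id] = [
                _record_to_json(r, q.client_has_child)
                for r in sorted(recs, key=lambda r: r.index)
            ]
    return {
        "format_version": FORMAT_VERSION,
        "client_has_child": q.client_has_child,
        "metadata": _metadata_to_json(q.metadata),
        "key_table": [
            {"label": e.label, "checked": e.checked,
             "show_below_symbol": e.show_below_symbol,
             "shade_index": e.shade_index}
            for e in q.key_table.entries
        ],
        "records": records,
    }


def questionnaire_from_json(d: dict) -> Questionnaire:
    known = {"format_version", "client_has_child", "metadata", "key_table",
             "records"}
    unknown = set(d) - known
    if unknown:
        raise QuestionnaireError(f"top level: unknown fields {sorted(unknown)}")
    version = d.get("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise QuestionnaireError(f"unsupported format_version {version!r}")
    if "client_has_child" not in d:
        raise QuestionnaireError("missing required field client_has_child")
    q = Questionnaire(
        client_has_child=bool(d["client_has_child"]),
        metadata=_metadata_from_json(d.get("metadata", {})),
    )
    kt = d.get("key_table")
    if kt is not None:
        if len(kt) != KEY_TABLE_SIZE:
            raise QuestionnaireError(
                f"key_table: expected {KEY_TABLE_SIZE} entries, got {len(kt)}")
        q.key_table = KeyTable(entries=[
            KeyEntry(label=str(e.get("label", "")),
                     checked=bool(e.get("checked", False)),
                     show_below_symbol=bool(e.get("show_below_symbol", False)),
                     shade_index=int(e.get("shade_index",
                                           i + 1 if i < CONDITION_KEY_CAP else 0)))
            for i, e in enumerate(kt)
        ])
    for slot_id, recs in d.get("records", {}).items():
        slot_def(slot_id)  # rejects unknown slots
        if isinstance(recs, dict):
            recs = [recs]
        for j, rd in enumerate(recs):
            rd = dict(rd)
            rd.setdefault("index", j + 1)
            q.put(_record_from_json(slot_id, rd, f"{slot_id}[{rd['index']}]"))
    validate_questionnaire(q)
    return q


# ---------------------------------------------------------------------------
# CSV interview-sheet dialect

CSV_HEADER = [
    "section", "slot", "index", "name", "age", "sex", "affected",
    "presymptomatic_carrier", "carrier", "deceased", "condition_keys",
    "infertility", "no_children_by_choice", "pregnancy", "fetal_status",
    "gestational_age_weeks", "multiple_gestation_id", "monozygotic",
    "custody", "multiple_individuals", "adoption", "donor_surrogate",
    "consanguinity", "overlay_id", "proband", "consultand",
    "history_unknown", "parent_index", "of_divorced_partner",
    "divorced_side", "show_below", "remarks",
]

_YESNO = {True: "yes", False: "no"}


def _yn(v, where: str) -> bool:
    if v in ("yes", "no", ""):
        return v == "yes"
    raise QuestionnaireError(f"{where}: expected yes/no, got {v!r}")


def _csv_record_row(r: PersonRecord, has_child: bool) -> list[str]:
    gs = set(r.general_status)
    return [
        "record", r.slot_id, str(r.index), r.name or r.default_name(has_child),
        r.age.display(), r.sex.value if r.sex is not None else "",
        _YESNO["affected" in gs], _YESNO["presymptomatic_carrier" in gs],
        _YESNO["carrier" in gs], _YESNO["deceased" in gs],
        ";".join(str(k) for k in r.condition_key_refs),
        _YESNO[r.infertility], _YESNO[r.no_children_by_choice],
        _YESNO[r.pregnancy], r.fetal_status if r.fetal_status != "none" else "",
        r.gestational_age.display().removesuffix("wk"),
        "" if r.multiple_gestation_id is None else str(r.multiple_gestation_id),
        _YESNO[r.monozygotic], _YESNO[r.custody_flag],
        "" if r.multiple_individuals == 1 else str(r.multiple_individuals),
        r.adoption.value if r.adoption != Adoption.NONE else "",
        r.donor_surrogate.value if r.donor_surrogate != GameteRole.NONE else "",
        _YESNO[r.consanguinity_flag],
        "" if r.overlay_id is None else str(r.overlay_id),
        _YESNO[r.is_proband], _YESNO[r.is_consultand],
        _YESNO[r.history_unknown],
        str(r.parent_index),
        "" if r.of_divorced_partner is None else str(r.of_divorced_partner),
        r.divorced_side, r.show_below, r.remarks,
    ]


def _csv_row_record(row: dict[str, str], rownum: int) -> PersonRecord:
    where = f"row {rownum} ({row.get('slot', '?')})"
    slot_id = row["slot"]
    slot_def(slot_id)
    gs = [st for st, col in (
        ("affected", "affected"),
        ("presymptomatic_carrier", "presymptomatic_carrier"),
        ("carrier", "carrier"),
        ("deceased", "deceased"),
    ) if _yn(row.get(col, ""), f"{where}.{col}")]
    age = row.get("age", "")
    gw = row.get("gestational_age_weeks", "")
    mi = row.get("multiple_individuals", "")
    try:
        return PersonRecord(
            slot_id=slot_id,
            index=int(row.get("index") or 1),
            name=row.get("name", ""),
            age=_age_from_json(age or None, where),
            sex=Sex(row["sex"]) if row.get("sex") else None,
            general_status=gs,
            condition_key_refs=[int(k) for k in row.get("condition_keys", "").split(";") if k],
            infertility=_yn(row.get("infertility", ""), where),
            no_children_by_choice=_yn(row.get("no_children_by_choice", ""), where),
            pregnancy=_yn(row.get("pregnancy", ""), where),
            fetal_status=row.get("fetal_status") or "none",
            gestational_age=_gest_from_json(gw or None, where),
            multiple_gestation_id=int(row["multiple_gestation_id"])
            if row.get("multiple_gestation_id") else None,
            monozygotic=_yn(row.get("monozygotic", ""), where),
            custody_flag=_yn(row.get("custody", ""), where),
            multiple_individuals=(1 if not mi else
                                  N_UNKNOWN if mi == N_UNKNOWN else int(mi)),
            adoption=Adoption(row.get("adoption") or "none"),
            donor_surrogate=GameteRole(row.get("donor_surrogate") or "none"),
            consanguinity_flag=_yn(row.get("consanguinity", ""), where),
            overlay_id=int(row["overlay_id"]) if row.get("overlay_id") else None,
            is_proband=_yn(row.get("proband", ""), where),
            is_consultand=_yn(row.get("consultand", ""), where),
            history_unknown=_yn(row.get("history_unknown", ""), where),
            parent_index=int(row.get("parent_index") or 1),
            of_divorced_partner=int(row["of_divorced_partner"])
            if row.get("of_divorced_partner") else None,
            divorced_side=row.get("divorced_side", ""),
            show_below=row.get("show_below", ""),
            remarks=row.get("remarks", ""),
        )
    except QuestionnaireError:
        raise
    except ValueError as e:
        raise QuestionnaireError(f"{where}: {e}") from None


def _pad(cells: list[str]) -> list[str]:
    return cells + [""] * (len(CSV_HEADER) - len(cells))


def write_questionnaire_csv(q: Questionnaire, out: TextIO) -> None:
    validate_questionnaire(q)
    w = csv.writer(out, lineterminator="\n")
    w.writerow(CSV_HEADER)
    w.writerow(_pad(["meta", "format_version", "", FORMAT_VERSION]))
    w.writerow(_pad(["meta", "client_has_child", "",
                     _YESNO[q.client_has_child]]))
    for k, v in _metadata_to_json(q.metadata).items():
        w.writerow(_pad(["meta", k, "", "" if v is None else str(v)]))
    for i, e in enumerate(q.key_table.entries, start=1):
        w.writerow(_pad(["key", str(i), "", e.label, _YESNO[e.checked],
                         _YESNO[e.show_below_symbol], str(e.shade_index)]))
    for r in q.all_records():
        w.writerow(_csv_record_row(r, q.client_has_child))


def read_questionnaire_csv(src: TextIO) -> Questionnaire:
    rows = list(csv.reader(src))
    if not rows or rows[0] != CSV_HEADER:
        raise QuestionnaireError("CSV header does not match the interview-sheet "
                                 "dialect")
    q = Questionnaire(client_has_child=True)
    meta: dict[str, str] = {}
    keys: dict[int, KeyEntry] = {}
    for n, cells in enumerate(rows[1:], start=2):
        if not any(cells):
            continue
        cells = _pad(list(cells))
        section = cells[0]
        if section == "meta":
            meta[cells[1]] = cells[3]
        elif section == "key":
            slot = int(cells[1])
            keys[slot] = KeyEntry(label=cells[3],
                                  checked=_yn(cells[4], f"row {n} key"),
                                  show_below_symbol=_yn(cells[5], f"row {n} key"),
                                  shade_index=int(cells[6] or 0))
        elif section == "record":
            row = dict(zip(CSV_HEADER, cells))
            q.put(_csv_row_record(row, n))
        else:
            raise QuestionnaireError(f"row {n}: unknown section {section!r}")
    version = meta.pop("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise QuestionnaireError(f"unsupported format_version {version!r}")
    if "client_has_child" not in meta:
        raise QuestionnaireError("missing meta row client_has_child")
    q.client_has_child = _yn(meta.pop("client_has_child"), "client_has_child")
    q.metadata = _metadata_from_json(
        {k: (v or None if k == "date_of_intake" else v) for k, v in meta.items()})
    if keys:
        if sorted(keys) != list(range(1, KEY_TABLE_SIZE + 1)):
            raise QuestionnaireError(
                f"key table rows must cover slots 1..{KEY_TABLE_SIZE}")
        q.key_table = KeyTable(entries=[keys[i]
                                        for i in range(1, KEY_TABLE_SIZE + 1)])
    validate_questionnaire(q)
    return q


# ---------------------------------------------------------------------------
# unified entry points


def write_questionnaire(q: Questionnaire, fmt: str = "json") -> str:
    """Serialize to the requested dialect; output is byte-deterministic."""
    if fmt == "json":
        return json.dumps(questionnaire_to_json(q), indent=2,
                          ensure_ascii=False) + "\n"
    if fmt == "csv":
        buf = io.StringIO()
        write_questionnaire_csv(q, buf)
        return buf.getvalue()
    raise ValueError(f"unknown questionnaire format {fmt!r}")


def read_questionnaire(source: TUnion[str, TextIO], fmt: str = "json") -> Questionnaire:
    if hasattr(source, "read"):
        source = source.read()
    if fmt == "json":
        try:
            data = json.loads(source)
        except json.JSONDecodeError as e:
            raise QuestionnaireError(f"invalid JSON: {e}") from None
        return questionnaire_from_json(data)
    if fmt == "csv":
        return read_questionnaire_csv(io.StringIO(source))
    raise ValueError(f"unknown questionnaire format {fmt!r}")
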