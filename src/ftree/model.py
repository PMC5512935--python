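"""Core pedigree graph model and structural validation.

A medical pedigree is a graph of :class:`Individual` nodes connected by
:class:`Union` (partnership) edges and :class:`Sibship` (parent-to-children)
hyperedges, restricted to three generations.  Generations are stored as
integers 1-3 (1 = oldest) and rendered as Roman numerals I-III only at
display time.

Pregnancy losses (spontaneous abortion, termination, ectopic pregnancy) are
ordinary :class:`Individual` nodes with a dedicated life stage: they occupy
sibship positions and may carry affected status.  Stillbirth and ectopic
pregnancy additionally carry auto-generated "SB"/"ECT" annotations, matching
the remarks-based convention for symbols the nomenclature expresses through
annotation text.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Union as TUnion

import networkx as nx

MAX_GENERATIONS = 3
MAX_AGE_YEARS = 130
MAX_GESTATION_WEEKS = 45
CONDITION_KEY_CAP = 4
KEY_TABLE_SIZE = 16
ROMAN = ("I", "II", "III")


class PedigreeStructureError(ValueError):
    """An id referenced by a union/sibship/mark does not resolve."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class LifeStage(str, enum.Enum):
    LIVING = "living"
    DECEASED = "deceased"
    PREGNANCY = "pregnancy"
    SAB = "SAB"            # spontaneous abortion
    TOP = "TOP"            # termination of pregnancy
    STILLBIRTH = "stillbirth"
    ECTOPIC = "ectopic"


#: life stages drawn as a small triangle (pregnancies not carried to term)
PREGNANCY_LOSS_STAGES = frozenset(
    {LifeStage.SAB, LifeStage.TOP, LifeStage.ECTOPIC}
)
#: life stages marked with a diagonal slash through the symbol
SLASHED_STAGES = frozenset(
    {LifeStage.DECEASED, LifeStage.STILLBIRTH, LifeStage.SAB, LifeStage.TOP}
)


class Adoption(str, enum.Enum):
    NONE = "none"
    ADOPTED_IN = "adopted_in"
    ADOPTED_OUT = "adopted_out"


class GameteRole(str, enum.Enum):
    NONE = "none"
    DONOR = "donor"
    SURROGATE = "surrogate"


class UnionStatus(str, enum.Enum):
    PARTNERED = "partnered"
    SEPARATED = "separated"
    DIVORCED = "divorced"


class Custody(str, enum.Enum):
    NONE = "none"
    PARTNER_A = "partner_a"
    PARTNER_B = "partner_b"
    SHARED = "shared"


class Zygosity(str, enum.Enum):
    MONOZYGOTIC = "monozygotic"
    DIZYGOTIC = "dizygotic"
    TRIZYGOTIC = "trizygotic"
    UNKNOWN = "unknown"


#: multiple_count sentinel for "n individuals, number unknown"
N_UNKNOWN = "n"


@dataclass(frozen=True)
class AgeValue:
    """Age answer: left blank, explicitly unknown ("?"), or a year count."""

    kind: str = "blank"  # blank | unknown | years
    years: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("blank", "unknown", "years"):
            raise ValueError(f"bad age kind {self.kind!r}")
        if self.kind == "years":
            if self.years is None or not (0 <= self.years <= MAX_AGE_YEARS):
                raise ValueError(f"age years out of range: {self.years!r}")
        elif self.years is not None:
            raise ValueError("years only allowed when kind='years'")

    @classmethod
    def blank(cls) -> "AgeValue":
        return cls("blank")

    @classmethod
    def unknown(cls) -> "AgeValue":
        return cls("unknown")

    @classmethod
    def of(cls, years: int) -> "AgeValue":
        return cls("years", years)

    def display(self) -> str:
        if self.kind == "blank":
            return ""
        if self.kind == "unknown":
            return "?"
        return str(self.years)


@dataclass(frozen=True)
class GestationalAge:
    """Gestational age in completed weeks; displays with a "wk" suffix."""

    kind: str = "blank"  # blank | unknown | weeks
    weeks: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("blank", "unknown", "weeks"):
            raise ValueError(f"bad gestational-age kind {self.kind!r}")
        if self.kind == "weeks":
            if self.weeks is None or not (0 <= self.weeks <= MAX_GESTATION_WEEKS):
                raise ValueError(f"gestation weeks out of range: {self.weeks!r}")
        elif self.weeks is not None:
            raise ValueError("weeks only allowed when kind='weeks'")

    @classmethod
    def blank(cls) -> "GestationalAge":
        return cls("blank")

    @classmethod
    def unknown(cls) -> "GestationalAge":
        return cls("unknown")

    @classmethod
    def of(cls, weeks: int) -> "GestationalAge":
        return cls("weeks", weeks)

    def display(self) -> str:
        if self.kind == "blank":
            return ""
        if self.kind == "unknown":
            return "?wk"
        return f"{self.weeks}wk"


@dataclass
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    name: str = ""
    age: AgeValue = field(default_factory=AgeValue.blank)
    generation: int = 3
    life_stage: LifeStage = LifeStage.LIVING
    affected: bool = False
    condition_keys: list[int] = field(default_factory=list)
    carrier: bool = False
    presymptomatic_carrier: bool = False
    is_proband: bool = False
    is_consultand: bool = False
    multiple_count: TUnion[int, str] = 1  # 1, k>=2, or N_UNKNOWN
    adoption: Adoption = Adoption.NONE
    gamete_role: GameteRole = GameteRole.NONE
    history_unknown: bool = False
    gestational_age: GestationalAge = field(default_factory=GestationalAge.blank)
    annotations: list[str] = field(default_factory=list)
    show_below: str = ""
    # deterministic left-to-right ordering hint assigned by the builder
    order_key: int = 0
    # Roman-numeral labels filled in by assign_identifiers
    gen_label: str = ""
    number: int = 0

    @property
    def label(self) -> str:
        """Display label like "II-3" once identifiers are assigned."""
        if self.gen_label and self.number:
            return f"{self.gen_label}-{self.number}"
        return self.id


@dataclass
class Union:
    id: str
    partner_a: str
    partner_b: str
    status: UnionStatus = UnionStatus.PARTNERED
    consanguineous: bool = False
    custody: Custody = Custody.NONE
    no_children_by_choice: bool = False
    infertility: bool = False

    @property
    def partners(self) -> tuple[str, str]:
        return (self.partner_a, self.partner_b)


@dataclass
class TwinGroup:
    members: list[str]
    zygosity: Zygosity = Zygosity.UNKNOWN


@dataclass
class Sibship:
    id: str
    union_id: Optional[str]  # None: free sibling line (parents out of frame)
    children: list[str] = field(default_factory=list)  # eldest first
    twin_groups: list[TwinGroup] = field(default_factory=list)


@dataclass
class KeyEntry:
    label: str = ""
    checked: bool = False
    show_below_symbol: bool = False
    shade_index: int = 0


@dataclass
class KeyTable:
    """Sixteen disease/feature entry fields; slots 1-4 double as condition keys."""

    entries: list[KeyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            self.entries = [
                KeyEntry(shade_index=i + 1 if i < CONDITION_KEY_CAP else 0)
                for i in range(KEY_TABLE_SIZE)
            ]

    def entry(self, slot: int) -> KeyEntry:
        """1-based slot access."""
        return self.entries[slot - 1]

    def checked_labels(self) -> list[str]:
        return [e.label for e in self.entries if e.checked]


@dataclass
class PedigreeMetadata:
    family_names: str = ""
    paternal_ancestry: str = ""
    maternal_ancestry: str = ""
    date_of_intake: Optional[date] = None
    historian: str = ""
    reason_for_pedigree: str = ""
    remarks: str = ""


@dataclass
class Comment:
    id: str
    text: str
    anchor: TUnion[str, tuple[float, float]]


@dataclass
class Pedigree:
    individuals: dict[str, Individual] = field(default_factory=dict)
    unions: dict[str, Union] = field(default_factory=dict)
    sibships: dict[str, Sibship] = field(default_factory=dict)
    proband_id: Optional[str] = None
    consultand_ids: list[str] = field(default_factory=list)
    metadata: PedigreeMetadata = field(default_factory=PedigreeMetadata)
    key_table: KeyTable = field(default_factory=KeyTable)
    comments: list[Comment] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------

    def add(self, obj: TUnion[Individual, Union, Sibship]) -> None:
        if isinstance(obj, Individual):
            self.individuals[obj.id] = obj
        elif isinstance(obj, Union):
            self.unions[obj.id] = obj
        elif isinstance(obj, Sibship):
            self.sibships[obj.id] = obj
        else:  # pragma: no cover - defensive
            raise TypeError(type(obj))

    def sibship_of_child(self, ind_id: str) -> Optional[Sibship]:
        for s in self.sibships.values():
            if ind_id in s.children:
                return s
        return None

    def parents_of(self, ind_id: str) -> tuple[str, ...]:
        s = self.sibship_of_child(ind_id)
        if s is None or s.union_id is None:
            return ()
        u = self.unions[s.union_id]
        return u.partners

    def unions_of(self, ind_id: str) -> list[Union]:
        return [u for u in self.unions.values() if ind_id in u.partners]

    def sibship_of_union(self, union_id: str) -> Optional[Sibship]:
        for s in self.sibships.values():
            if s.union_id == union_id:
                return s
        return None


@dataclass(frozen=True, order=True)
class Violation:
    severity: str  # "error" sorts before "warning"
    subject: str
    code: str
    message: str = field(compare=False)


def _v(code: str, severity: str, subject: str, message: str) -> Violation:
    return Violation(severity=severity, subject=subject, code=code, message=message)


def _check_resolution(p: Pedigree) -> None:
    ids = p.individuals.keys()
    for u in p.unions.values():
        for pid in u.partners:
            if pid not in ids:
                raise PedigreeStructureError(
                    f"union {u.id} references unknown individual {pid!r}"
                )
    for s in p.sibships.values():
        if s.union_id is not None and s.union_id not in p.unions:
            raise PedigreeStructureError(
                f"sibship {s.id} references unknown union {s.union_id!r}"
            )
        for cid in s.children:
            if cid not in ids:
                raise PedigreeStructureError(
                    f"sibship {s.id} references unknown child {cid!r}"
                )
    if p.proband_id is not None and p.proband_id not in ids:
        raise PedigreeStructureError(f"proband {p.proband_id!r} not in pedigree")
    for cid in p.consultand_ids:
        if cid not in ids:
            raise PedigreeStructureError(f"consultand {cid!r} not in pedigree")


def _descent_graph(p: Pedigree) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(p.individuals)
    for s in p.sibships.values():
        parents = p.unions[s.union_id].partners if s.union_id else ()
        for parent in parents:
            for child in s.children:
                g.add_edge(parent, child)
    return g


def validate_pedigree(p: Pedigree) -> list[Violation]:
    """Check every structural invariant; return a stable-ordered violation list.

    Unresolved id references are a structural defect and raise
    :class:`PedigreeStructureError` instead of being reported as violations.
    The function is pure: repeated calls return identical lists.
    """
    _check_resolution(p)
    out: list[Violation] = []

    # -- individuals ------------------------------------------------------
    for i in p.individuals.values():
        if not (1 <= i.generation <= MAX_GENERATIONS):
            out.append(_v("GENERATION_RANGE", "error", i.id,
                          f"generation {i.generation} outside 1..{MAX_GENERATIONS}"))
        if len(i.condition_keys) > CONDITION_KEY_CAP:
            out.append(_v("CONDITION_CAP", "error", i.id,
                          f"{len(i.condition_keys)} condition keys exceed the cap "
                          f"of {CONDITION_KEY_CAP}"))
        if any(not (1 <= k <= CONDITION_KEY_CAP) for k in i.condition_keys):
            out.append(_v("KEY_REF_RANGE", "error", i.id,
                          "condition keys must reference key-table slots 1-4"))
        if i.affected != bool(i.condition_keys):
            out.append(_v("AFFECTED_KEYS", "error", i.id,
                          "affected flag inconsistent with condition keys"))
        if i.carrier and i.presymptomatic_carrier:
            out.append(_v("CARRIER_CONFLICT", "error", i.id,
                          "carrier and presymptomatic carrier are mutually "
                          "exclusive"))
        if i.life_stage in PREGNANCY_LOSS_STAGES and p.sibship_of_child(i.id) is None:
            out.append(_v("LOSS_UNATTACHED", "error", i.id,
                          f"{i.life_stage.value} node must sit in its parents' "
                          "sibship"))
        if i.multiple_count != 1 and (i.is_proband or i.is_consultand):
            out.append(_v("MULTIPLE_MARK", "error", i.id,
                          "a multiple-individuals node cannot be proband or "
                          "consultand"))
        if i.multiple_count != 1 and i.life_stage == LifeStage.PREGNANCY:
            out.append(_v("MULTIPLE_PREGNANCY", "error", i.id,
                          "a multiple-individuals node cannot hold pregnancy "
                          "status"))
        if isinstance(i.multiple_count, int) and i.multiple_count < 1:
            out.append(_v("MULTIPLE_COUNT", "error", i.id,
                          "multiple count must be >= 1"))

    # -- unions -----------------------------------------------------------
    for u in p.unions.values():
        if u.partner_a == u.partner_b:
            out.append(_v("SELF_PARTNER", "error", u.id,
                          "union partners must differ"))
        if u.custody != Custody.NONE and u.status != UnionStatus.DIVORCED:
            out.append(_v("CUSTODY_STATUS", "error", u.id,
                          "custody applies to divorced unions only"))
        sib = p.sibship_of_union(u.id)
        if (u.no_children_by_choice or u.infertility) and sib and sib.children:
            out.append(_v("CHILDLESS_CONTRADICTION", "error", u.id,
                          "union flagged childless/infertile but has children"))

    # -- sibships ---------------------------------------------------------
    seen_as_child: dict[str, str] = {}
    for s in p.sibships.values():
        for cid in s.children:
            if cid in seen_as_child:
                out.append(_v("MULTI_SIBSHIP", "error", cid,
                              "individual is a child in more than one sibship"))
            seen_as_child[cid] = s.id
        if s.union_id is not None:
            parents = [p.individuals[q] for q in p.unions[s.union_id].partners]
            child_gen = max(x.generation for x in parents) + 1
            for cid in s.children:
                if p.individuals[cid].generation != child_gen:
                    out.append(_v("CHILD_GENERATION", "error", cid,
                                  f"child generation must be {child_gen}"))
        else:
            gens = {p.individuals[cid].generation for cid in s.children}
            if len(gens) > 1:
                out.append(_v("SIBLING_GENERATION", "error", s.id,
                              "parentless sibship spans several generations"))
        for tg in s.twin_groups:
            idx = [s.children.index(m) for m in tg.members if m in s.children]
            if len(idx) != len(tg.members) or sorted(idx) != list(
                range(min(idx), min(idx) + len(idx))
            ):
                out.append(_v("TWIN_NONCONSECUTIVE", "error", s.id,
                              "twin-group members must be consecutive siblings"))
            if tg.zygosity == Zygosity.MONOZYGOTIC:
                sexes = {p.individuals[m].sex for m in tg.members
                         if m in p.individuals}
                if len(sexes) > 1:
                    out.append(_v("ZYGOSITY_SEX", "error", s.id,
                                  "monozygotic twins must share one sex"))

    # -- whole pedigree ---------------------------------------------------
    levels = {i.generation for i in p.individuals.values()}
    if len(levels) > MAX_GENERATIONS:
        out.append(_v("GENERATION_LIMIT", "error", "pedigree",
                      f"{len(levels)} generation levels exceed the "
                      f"three-generation frame"))
    if p.individuals and not nx.is_directed_acyclic_graph(_descent_graph(p)):
        out.append(_v("DESCENT_CYCLE", "error", "pedigree",
                      "descent edges form a cycle"))
    if len(p.key_table.entries) != KEY_TABLE_SIZE:
        out.append(_v("KEY_TABLE_SIZE", "error", "key_table",
                      f"key table must have exactly {KEY_TABLE_SIZE} slots"))
    else:
        shades = [e.shade_index for e in p.key_table.entries[:CONDITION_KEY_CAP]]
        if len(set(shades)) != len(shades):
            out.append(_v("SHADE_DUPLICATE", "error", "key_table",
                          "shade indices of key slots 1-4 must be distinct"))
    if p.individuals and p.proband_id is None:
        out.append(_v("NO_PROBAND", "warning", "pedigree",
                      "no proband designated"))

    return sorted(out)


def generation_count(p: Pedigree) -> int:
    """Number of distinct generation levels occupied (0 for an empty graph)."""
    return len({i.generation for i in p.individuals.values()})


def occupied_levels(p: Pedigree) -> list[int]:
    return sorted({i.generation for i in p.individuals.values()})


def roman_label(p: Pedigree, generation: int) -> str:
    """Roman numeral for a generation level, ranked among occupied levels."""
    levels = occupied_levels(p)
    return ROMAN[levels.index(generation)]
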