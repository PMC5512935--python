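"""Per-feature compliance checks backing :func:`ftree.symbols.compliance_report`.

Each check constructs a minimal pedigree (or individual/union) exhibiting one
nomenclature feature, runs it through the real pipeline pieces — glyph
derivation, line styling, layout, rendering — and verifies the feature is
expressed in the output.  Features the chart expresses through annotation
text (remarks) are checked in ``below_text``/rendered text.
"""

from __future__ import annotations

from datetime import date

from .layout import compute_layout
from .model import (
    AgeValue,
    Adoption,
    Custody,
    GameteRole,
    Individual,
    KeyTable,
    LifeStage,
    N_UNKNOWN,
    Pedigree,
    PedigreeMetadata,
    Sex,
    Sibship,
    TwinGroup,
    Union,
    UnionStatus,
    Zygosity,
    validate_pedigree,
)
from .render import RenderOptions, render_svg
from .symbols import ShadePalette, symbol_for, union_line_style

_KT = KeyTable()
_KT.entry(1).label, _KT.entry(1).checked = "condition A", True
_KT.entry(2).label, _KT.entry(2).checked = "condition B", True
_PALETTE = ShadePalette()


def _sym(**kw):
    return symbol_for(Individual(id="x", **kw), _KT, _PALETTE)


def _couple_with_children(children: list[Individual],
                          twin_groups=None) -> Pedigree:
    p = Pedigree(key_table=_KT)
    f = Individual(id="f", sex=Sex.MALE, generation=2, order_key=1)
    m = Individual(id="m", sex=Sex.FEMALE, generation=2, order_key=2)
    p.add(f), p.add(m)
    p.add(Union(id="u1", partner_a="f", partner_b="m"))
    for n, c in enumerate(children, start=3):
        c.generation = 3
        c.order_key = n
        p.add(c)
    s = Sibship(id="s1", union_id="u1", children=[c.id for c in children])
    s.twin_groups = twin_groups or []
    p.add(s)
    return p


def _errors(p: Pedigree) -> list:
    return [v for v in validate_pedigree(p) if v.severity == "error"]


def _render(p: Pedigree, **opts) -> str:
    return render_svg(compute_layout(p), p, RenderOptions(**opts))


def _twins(zygosity: Zygosity, n: int = 2, sex: Sex = Sex.FEMALE) -> bool:
    kids = [Individual(id=f"c{i}", sex=sex) for i in range(n)]
    p = _couple_with_children(
        kids, [TwinGroup(members=[c.id for c in kids], zygosity=zygosity)])
    if _errors(p):
        return False
    lay = compute_layout(p)
    twin_lines = [ln for ln in lay.lines if ln.kind == "twin"]
    bar = [ln for ln in lay.lines if ln.kind == "twin_bar"]
    apexes = {ln.points[0] for ln in twin_lines}
    ok = len(twin_lines) == n and len(apexes) == 1
    if zygosity == Zygosity.MONOZYGOTIC:
        ok = ok and len(bar) == 1
    if zygosity == Zygosity.UNKNOWN:
        # zygosity noted in annotation text next to the twin symbols
        for c in p.individuals.values():
            if c.generation == 3:
                c.annotations.append("zygosity ?")
        ok = ok and "zygosity ?" in _render(p)
    return ok


def _check_name_marks() -> bool:
    i = Individual(id="x", sex=Sex.FEMALE, name="A. Proband", is_proband=True)
    spec = symbol_for(i, _KT, _PALETTE)
    p = Pedigree(key_table=_KT)
    p.add(i)
    p.proband_id = "x"
    return spec.arrow == "proband" and "A. Proband" in _render(
        p, show_names=True)


def _check_metadata(field: str, value, needle: str) -> bool:
    p = Pedigree(key_table=_KT, metadata=PedigreeMetadata(**{field: value}))
    p.add(Individual(id="x", sex=Sex.MALE))
    return needle in _render(p)


def _check_generation_labels() -> bool:
    p = _couple_with_children([Individual(id="c", sex=Sex.MALE)])
    from .builder import assign_identifiers

    assign_identifiers(p)
    labels = {i.label for i in p.individuals.values()}
    return labels == {"I-1", "I-2", "II-1"} and ">I<" in _render(p)


def _check_numbering() -> bool:
    p = _couple_with_children([Individual(id=f"c{i}", sex=Sex.UNKNOWN)
                               for i in range(3)])
    from .builder import assign_identifiers

    assign_identifiers(p)
    return [p.individuals[f"c{i}"].number for i in range(3)] == [1, 2, 3]


def _check_divorced() -> bool:
    u = Union(id="u", partner_a="a", partner_b="b",
              status=UnionStatus.DIVORCED, custody=Custody.PARTNER_A)
    st = union_line_style(u)
    return st.double_slash and st.custody_break_offset == 2 / 3


def _check_childless(infertile: bool) -> bool:
    p = Pedigree(key_table=_KT)
    p.add(Individual(id="a", sex=Sex.MALE, generation=2, order_key=1))
    p.add(Individual(id="b", sex=Sex.FEMALE, generation=2, order_key=2))
    p.add(Union(id="u", partner_a="a", partner_b="b",
                infertility=infertile, no_children_by_choice=not infertile))
    if _errors(p):
        return False
    kinds = {ln.kind for ln in compute_layout(p).lines}
    return ("infertility" if infertile else "childless") in kinds


def _check_adoption() -> bool:
    child = Individual(id="c", sex=Sex.FEMALE, adoption=Adoption.ADOPTED_IN)
    spec = symbol_for(child, _KT, _PALETTE)
    p = _couple_with_children([child])
    kinds = {ln.kind for ln in compute_layout(p).lines}
    return spec.brackets and "adoption_dashed" in kinds


def _check_annotation(text: str, **kw) -> bool:
    i = Individual(id="x", annotations=[text], **kw)
    return text in symbol_for(i, _KT, _PALETTE).below_text


CHECKS = {
    "name_of_proband_consultand": _check_name_marks,
    "family_names": lambda: _check_metadata("family_names", "Yamada",
                                            "Family: Yamada"),
    "historian": lambda: _check_metadata("historian", "K.Y.",
                                         "Historian: K.Y."),
    "date_of_intake": lambda: _check_metadata(
        "date_of_intake", date(2017, 7, 14), "2017-07-14"),
    "reason_for_pedigree": lambda: _check_metadata(
        "reason_for_pedigree", "counseling", "Reason: counseling"),
    "ancestry": lambda: (_check_metadata("paternal_ancestry", "Tohoku",
                                         "Paternal ancestry: Tohoku") and
                         _check_metadata("maternal_ancestry", "Kansai",
                                         "Maternal ancestry: Kansai")),
    "age": lambda: "34" in _sym(sex=Sex.FEMALE,
                                age=AgeValue.of(34)).below_text,
    "generation_roman_numerals": _check_generation_labels,
    "individual_numbered": _check_numbering,
    "individual": lambda: (_sym(sex=Sex.MALE).shape == "square" and
                           _sym(sex=Sex.FEMALE).shape == "circle" and
                           _sym(sex=Sex.UNKNOWN).shape == "diamond"),
    "affected_individual": lambda: _sym(
        sex=Sex.MALE, affected=True, condition_keys=[1]).fill == ((1, 1),),
    "affected_multiple_conditions": lambda: _sym(
        sex=Sex.FEMALE, affected=True,
        condition_keys=[1, 2]).fill == ((1, 1), (2, 2)),
    "multiple_individuals_known": lambda: _sym(
        sex=Sex.MALE, multiple_count=5).letter == "5",
    "multiple_individuals_unknown": lambda: _sym(
        sex=Sex.MALE, multiple_count=N_UNKNOWN).letter == "n",
    "deceased_individual": lambda: _sym(
        sex=Sex.MALE, life_stage=LifeStage.DECEASED).slash,
    "consultand": lambda: _sym(sex=Sex.FEMALE,
                               is_consultand=True).arrow == "consultand",
    "proband": lambda: _sym(sex=Sex.MALE, is_proband=True).arrow == "proband",
    "stillbirth": lambda: (
        _sym(sex=Sex.FEMALE, life_stage=LifeStage.STILLBIRTH,
             annotations=["SB"]).slash and
        _check_annotation("SB", sex=Sex.FEMALE,
                          life_stage=LifeStage.STILLBIRTH)),
    "pregnancy": lambda: (lambda s: s.letter == "P" and
                          s.shape == "diamond")(
        _sym(sex=Sex.UNKNOWN, life_stage=LifeStage.PREGNANCY)),
    "spontaneous_abortion": lambda: (lambda s: s.shape == "triangle" and
                                     s.size_class == "small" and s.slash)(
        _sym(life_stage=LifeStage.SAB)),
    "affected_sab": lambda: bool(_sym(life_stage=LifeStage.SAB, affected=True,
                                      condition_keys=[1]).fill),
    "termination_of_pregnancy": lambda: (lambda s: s.shape == "triangle" and
                                         s.slash)(
        _sym(life_stage=LifeStage.TOP)),
    "affected_top": lambda: bool(_sym(life_stage=LifeStage.TOP, affected=True,
                                      condition_keys=[1]).fill),
    "ectopic_pregnancy": lambda: _check_annotation(
        "ECT", life_stage=LifeStage.ECTOPIC),
    "relationship_line": lambda: (lambda s: s.kind == "single" and
                                  not s.double_slash)(
        union_line_style(Union(id="u", partner_a="a", partner_b="b"))),
    "break_in_relationship_line": lambda: union_line_style(
        Union(id="u", partner_a="a", partner_b="b",
              status=UnionStatus.SEPARATED)).double_slash,
    "divorced_partner": _check_divorced,
    "consanguinity": lambda: union_line_style(
        Union(id="u", partner_a="a", partner_b="b",
              consanguineous=True)).kind == "double",
    "twins_monozygotic": lambda: _twins(Zygosity.MONOZYGOTIC),
    "twins_dizygotic": lambda: _twins(Zygosity.DIZYGOTIC),
    "twins_unknown_zygosity": lambda: _twins(Zygosity.UNKNOWN),
    "twins_trizygotic": lambda: _twins(Zygosity.TRIZYGOTIC, n=3),
    "family_history_unavailable": lambda: _sym(
        sex=Sex.MALE, history_unknown=True).question_mark_above,
    "no_children_by_choice": lambda: _check_childless(False),
    "infertility": lambda: _check_childless(True),
    "adoption": _check_adoption,
    "gamete_donor": lambda: _sym(sex=Sex.FEMALE,
                                 gamete_role=GameteRole.DONOR).letter == "D",
    "surrogate": lambda: _sym(sex=Sex.FEMALE,
                              gamete_role=GameteRole.SURROGATE).letter == "S",
    "evaluation": lambda: _check_annotation("E", sex=Sex.MALE),
    "carrier": lambda: _sym(sex=Sex.FEMALE, carrier=True).center_mark == "dot",
    "presymptomatic_carrier": lambda: _sym(
        sex=Sex.MALE,
        presymptomatic_carrier=True).center_mark == "vertical_line",
    "uninformative_study": lambda: _check_annotation("Eu", sex=Sex.FEMALE),
    "affected_with_positive_evaluation": lambda: (
        _check_annotation("E+", sex=Sex.MALE, affected=True,
                          condition_keys=[1]) and
        bool(_sym(sex=Sex.MALE, affected=True, condition_keys=[1],
                  annotations=["E+"]).fill)),
}
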