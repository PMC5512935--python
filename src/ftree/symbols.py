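"""Standardized pedigree nomenclature: per-individual glyphs and line styles.

``symbol_for`` is a total, deterministic function from a valid individual to
its glyph description: squares for males, circles for females, diamonds when
sex is unknown, small triangles for pregnancies not carried to term.  Affected
individuals are filled with luminance-stepped shades of a single configurable
key colour (one shade per condition key, up to four, filled clockwise from the
upper-left quadrant in key order) so that the chart stays legible after a
black-and-white photocopy.

Features the nomenclature expresses through annotation text (stillbirth "SB",
ectopic "ECT", evaluation marks "E"/"Eu"/"E+", unknown twin zygosity) travel
in ``below_text``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .model import (
    Custody,
    GameteRole,
    Individual,
    KeyTable,
    LifeStage,
    Adoption,
    N_UNKNOWN,
    PREGNANCY_LOSS_STAGES,
    SLASHED_STAGES,
    Sex,
    Union,
    UnionStatus,
)

_SHAPE_BY_SEX = {Sex.MALE: "square", Sex.FEMALE: "circle",
                 Sex.UNKNOWN: "diamond"}

#: target relative luminances of the four key shades; pairwise gaps >= 0.15
#: keep the shades distinguishable in a grayscale photocopy
_SHADE_LUMINANCE = (0.13, 0.32, 0.55, 0.82)


def _parse_color(color: str) -> tuple[float, float, float]:
    c = color.lstrip("#")
    if len(c) != 6:
        raise ValueError(f"expected #RRGGBB colour, got {color!r}")
    return tuple(int(c[i:i + 2], 16) / 255.0 for i in (0, 2, 4))


def _to_hex(rgb: tuple[float, float, float]) -> str:
    return "#" + "".join(f"{round(max(0.0, min(1.0, v)) * 255):02x}" for v in rgb)


def _linear(v: float) -> float:
    return v / 12.92 if v <= 0.04045 else ((v + 0.055) / 1.055) ** 2.4


def relative_luminance(color: str) -> float:
    """sRGB relative luminance in [0, 1] (the grayscale value of the colour)."""
    r, g, b = (_linear(v) for v in _parse_color(color))
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


def _mix(a: tuple[float, ...], b: tuple[float, ...], t: float) -> tuple[float, ...]:
    return tuple(x + (y - x) * t for x, y in zip(a, b))


def _shade_at(base: tuple[float, float, float], target: float) -> str:
    """Blend the base colour toward black or white to hit a target luminance."""
    base_lum = relative_luminance(_to_hex(base))
    other = (1.0, 1.0, 1.0) if target > base_lum else (0.0, 0.0, 0.0)
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if relative_luminance(_to_hex(_mix(base, other, mid))) < target:
            if other == (1.0, 1.0, 1.0):
                lo = mid
            else:
                hi = mid
        else:
            if other == (1.0, 1.0, 1.0):
                hi = mid
            else:
                lo = mid
    return _to_hex(_mix(base, other, (lo + hi) / 2))


@dataclass(frozen=True)
class ShadePalette:
    """Four luminance-stepped variants of a user-configured key colour."""

    base_color: str = "#c0392b"
    shades: tuple[str, str, str, str] = ()

    def __post_init__(self) -> None:
        if not self.shades:
            base = _parse_color(self.base_color)
            object.__setattr__(
                self, "shades",
                tuple(_shade_at(base, t) for t in _SHADE_LUMINANCE))

    def shade(self, shade_index: int) -> str:
        """1-based shade lookup (shade_index 0 falls back to the base colour)."""
        if 1 <= shade_index <= len(self.shades):
            return self.shades[shade_index - 1]
        return self.base_color


@dataclass(frozen=True)
class SymbolSpec:
    shape: str  # square | circle | diamond | triangle
    size_class: str = "standard"  # standard | small
    fill: tuple[tuple[int, int], ...] = ()  # (quadrant 1-4, shade_index)
    slash: bool = False
    center_mark: str = "none"  # none | dot | vertical_line | letter
    letter: str = ""
    brackets: bool = False
    arrow: str = "none"  # none | proband | consultand
    question_mark_above: bool = False
    below_text: tuple[str, ...] = ()


def symbol_for(i: Individual, key_table: KeyTable,
               palette: Optional[ShadePalette] = None) -> SymbolSpec:
    """Map a valid individual to its nomenclature glyph (total function)."""
    del palette  # shades resolve at render time; kept for API symmetry
    if i.life_stage in PREGNANCY_LOSS_STAGES:
        shape, size = "triangle", "small"
    else:
        shape, size = _SHAPE_BY_SEX[i.sex], "standard"

    fill: tuple[tuple[int, int], ...] = ()
    if i.affected:
        keys = sorted(i.condition_keys)
        fill = tuple((q + 1, key_table.entry(k).shade_index or k)
                     for q, k in enumerate(keys))

    center, letter = "none", ""
    if i.multiple_count != 1:
        center = "letter"
        letter = N_UNKNOWN if i.multiple_count == N_UNKNOWN else str(
            i.multiple_count)
    elif i.life_stage == LifeStage.PREGNANCY:
        center, letter = "letter", "P"
    elif i.gamete_role == GameteRole.DONOR:
        center, letter = "letter", "D"
    elif i.gamete_role == GameteRole.SURROGATE:
        center, letter = "letter", "S"
    elif i.carrier:
        center = "dot"
    elif i.presymptomatic_carrier:
        center = "vertical_line"

    below: list[str] = []
    if i.age.display():
        below.append(i.age.display())
    if i.gestational_age.display():
        below.append(i.gestational_age.display())
    if i.show_below:
        below.append(i.show_below)
    below.extend(i.annotations)

    arrow = "proband" if i.is_proband else (
        "consultand" if i.is_consultand else "none")
    return SymbolSpec(
        shape=shape,
        size_class=size,
        fill=fill,
        slash=i.life_stage in SLASHED_STAGES,
        center_mark=center,
        letter=letter,
        brackets=i.adoption != Adoption.NONE,
        arrow=arrow,
        question_mark_above=i.history_unknown,
        below_text=tuple(below),
    )


@dataclass(frozen=True)
class LineStyle:
    kind: str  # single | double
    double_slash: bool = False
    custody_break_offset: Optional[float] = None  # fraction from partner_a


def union_line_style(u: Union) -> LineStyle:
    """Relationship-line style: double when consanguineous, a double slash
    when the partnership is separated or divorced, with the break displaced
    toward the non-custodial partner."""
    kind = "double" if u.consanguineous else "single"
    broken = u.status in (UnionStatus.SEPARATED, UnionStatus.DIVORCED)
    offset: Optional[float] = None
    if broken:
        offset = {Custody.PARTNER_A: 2 / 3, Custody.PARTNER_B: 1 / 3}.get(
            u.custody, 0.5)
    return LineStyle(kind=kind, double_slash=broken,
                     custody_break_offset=offset)


# ---------------------------------------------------------------------------
# feature-matrix compliance


def load_feature_checklist() -> list[dict]:
    """The shipped machine-readable nomenclature feature checklist."""
    text = resources.files("ftree.data").joinpath(
        "nomenclature_features.json").read_text(encoding="utf-8")
    return json.loads(text)


def compliance_report(feature_checklist: Optional[list] = None) -> dict[str, bool]:
    """For each checklist feature, build a minimal pedigree exhibiting it,
    derive its glyph/line description (rendering where the feature lives in
    the chart furniture), and report support."""
    from . import _compliance

    checklist = feature_checklist or load_feature_checklist()
    out: dict[str, bool] = {}
    for row in checklist:
        fid = row["id"] if isinstance(row, dict) else row
        check = _compliance.CHECKS.get(fid)
        out[fid] = bool(check()) if check else False
    return out
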