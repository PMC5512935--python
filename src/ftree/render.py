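"""SVG chart output: glyphs, lines, numbering, legend, privacy defaults.

Output is SVG 1.1 built with the standard-library XML tree, so two renders of
the same layout/pedigree/options are byte-identical.  By default no name
entered on the questionnaire appears anywhere in the document — charts are
shared, names are not; ``show_names=True`` opts in.  Names left at the
relationship-label default are structural, never rendered as names.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .layout import LayoutResult
from .model import Pedigree, roman_label
from .symbols import ShadePalette, SymbolSpec, symbol_for

_DASH = "6,4"
_LINE_KIND_STYLE = {
    "relationship": {},
    "descent": {},
    "sibship": {},
    "twin": {},
    "twin_bar": {},
    "childless": {},
    "infertility": {},
    "adoption_dashed": {"stroke-dasharray": _DASH},
}


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class RenderOptions:
    show_names: bool = False  # privacy default: names stay out of the bytes
    include_legend: bool = True
    base_key_color: str = "#c0392b"
    scale: float = 1.0
    font_size: float = 11.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def _fmt(v: float) -> str:
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s if s != "-0" else "0"


def _el(parent: ET.Element, tag: str, **attrs: str) -> ET.Element:
    return ET.SubElement(parent, tag, dict(attrs))


def _line(parent: ET.Element, x1: float, y1: float, x2: float, y2: float,
          **attrs: str) -> ET.Element:
    return _el(parent, "line", x1=_fmt(x1), y1=_fmt(y1), x2=_fmt(x2),
               y2=_fmt(y2), stroke="black", **attrs)


def _text(parent: ET.Element, x: float, y: float, content: str,
          anchor: str = "middle", size: float = 11.0) -> ET.Element:
    t = _el(parent, "text", x=_fmt(x), y=_fmt(y))
    t.set("text-anchor", anchor)
    t.set("font-size", _fmt(size))
    t.set("font-family", "sans-serif")
    t.text = content
    return t


# ---------------------------------------------------------------------------
# glyph geometry


def _shape_outline(g: ET.Element, shape: str, x: float, y: float,
                   half: float) -> None:
    if shape == "square":
        _el(g, "rect", x=_fmt(x - half), y=_fmt(y - half),
            width=_fmt(2 * half), height=_fmt(2 * half),
            fill="none", stroke="black")
    elif shape == "circle":
        _el(g, "circle", cx=_fmt(x), cy=_fmt(y), r=_fmt(half),
            fill="none", stroke="black")
    elif shape == "diamond":
        pts = f"{_fmt(x)},{_fmt(y - half)} {_fmt(x + half)},{_fmt(y)} " \
              f"{_fmt(x)},{_fmt(y + half)} {_fmt(x - half)},{_fmt(y)}"
        _el(g, "polygon", points=pts, fill="none", stroke="black")
    elif shape == "triangle":
        pts = f"{_fmt(x)},{_fmt(y - half)} {_fmt(x + half)},{_fmt(y + half)} " \
              f"{_fmt(x - half)},{_fmt(y + half)}"
        _el(g, "polygon", points=pts, fill="none", stroke="black")
    else:  # pragma: no cover - defensive
        raise RenderError(f"unknown shape {shape!r}")


def _quadrant_path(shape: str, q: int, x: float, y: float, half: float) -> str:
    """Path for quadrant q (1..4, clockwise from upper-left)."""
    if shape == "circle":
        start = {1: (x - half, y), 2: (x, y - half),
                 3: (x + half, y), 4: (x, y + half)}[q]
        end = {1: (x, y - half), 2: (x + half, y),
               3: (x, y + half), 4: (x - half, y)}[q]
        return (f"M {_fmt(x)} {_fmt(y)} L {_fmt(start[0])} {_fmt(start[1])} "
                f"A {_fmt(half)} {_fmt(half)} 0 0 1 "
                f"{_fmt(end[0])} {_fmt(end[1])} Z")
    if shape == "square":
        x0 = x - half if q in (1, 4) else x
        y0 = y - half if q in (1, 2) else y
        return (f"M {_fmt(x0)} {_fmt(y0)} h {_fmt(half)} v {_fmt(half)} "
                f"h {_fmt(-half)} Z")
    if shape == "diamond":
        corner = {1: (x - half, y), 2: (x, y - half),
                  3: (x + half, y), 4: (x, y + half)}
        nxt = {1: 2, 2: 3, 3: 4, 4: 1}[q]
        ax, ay = corner[q]
        bx, by = corner[nxt]
        return (f"M {_fmt(x)} {_fmt(y)} L {_fmt(ax)} {_fmt(ay)} "
                f"L {_fmt(bx)} {_fmt(by)} Z")
    # triangle (pregnancy loss): affected fill sits below a horizontal bar
    return (f"M {_fmt(x - half / 2)} {_fmt(y)} L {_fmt(x + half / 2)} {_fmt(y)} "
            f"L {_fmt(x + half)} {_fmt(y + half)} "
            f"L {_fmt(x - half)} {_fmt(y + half)} Z")


def _glyph(parent: ET.Element, iid: str, spec: SymbolSpec, x: float, y: float,
           size: float, palette: ShadePalette, font: float) -> float:
    """Draw one individual's glyph; returns the y where below-text begins."""
    g = _el(parent, "g", id=f"ind-{iid}")
    g.set("class", f"individual {spec.shape}")
    half = size / 2 * (0.6 if spec.size_class == "small" else 1.0)

    if len(spec.fill) == 1:
        # a single condition fills the whole symbol
        q, shade = spec.fill[0]
        color = palette.shade(shade)
        if spec.shape == "square":
            _el(g, "rect", x=_fmt(x - half), y=_fmt(y - half),
                width=_fmt(2 * half), height=_fmt(2 * half), fill=color)
        elif spec.shape == "circle":
            _el(g, "circle", cx=_fmt(x), cy=_fmt(y), r=_fmt(half), fill=color)
        else:
            _el(g, "path", d=_quadrant_path(spec.shape, q, x, y, half),
                fill=color)
    else:
        for q, shade in spec.fill:
            _el(g, "path", d=_quadrant_path(spec.shape, q, x, y, half),
                fill=palette.shade(shade))
    _shape_outline(g, spec.shape, x, y, half)

    if spec.slash:
        _line(g, x - half - 4, y + half + 4, x + half + 4, y - half - 4)
    if spec.center_mark == "dot":
        _el(g, "circle", cx=_fmt(x), cy=_fmt(y), r=_fmt(half / 5),
            fill="black")
    elif spec.center_mark == "vertical_line":
        _line(g, x, y - half * 0.7, x, y + half * 0.7)
    elif spec.center_mark == "letter":
        _text(g, x, y + font * 0.35, spec.letter, size=font)
    if spec.brackets:
        for sgn in (-1, 1):
            bx = x + sgn * (half + 5)
            d = (f"M {_fmt(bx + sgn * -4)} {_fmt(y - half - 3)} "
                 f"L {_fmt(bx)} {_fmt(y - half - 3)} "
                 f"L {_fmt(bx)} {_fmt(y + half + 3)} "
                 f"L {_fmt(bx + sgn * -4)} {_fmt(y + half + 3)}")
            p = _el(g, "path", d=d, fill="none", stroke="black")
            p.set("class", "adoption-bracket")
    if spec.arrow != "none":
        # arrow to the lower left, per the nomenclature convention
        ax, ay = x - half - 14, y + half + 14
        ln = _line(g, ax, ay, x - half - 4, y + half + 4)
        ln.set("class", f"arrow-{spec.arrow}")
        _el(g, "path",
            d=(f"M {_fmt(x - half - 4)} {_fmt(y + half + 4)} "
               f"l -7 1.5 l 2.5 -6.5 Z"),
            fill="black")
        if spec.arrow == "proband":
            _text(g, ax - 4, ay + 6, "P", size=font)
    if spec.question_mark_above:
        _text(g, x, y - half - 5, "?", size=font)
    return y + half


# ---------------------------------------------------------------------------
# legend


def _legend_group(key_table, palette: ShadePalette, font: float) -> ET.Element:
    g = ET.Element("g", {"id": "legend"})
    row = 0
    for slot, entry in enumerate(key_table.entries, start=1):
        if not entry.checked:
            continue
        y = row * (font + 8)
        shade = palette.shade(entry.shade_index or slot)
        _el(g, "rect", x="0", y=_fmt(y), width=_fmt(font),
            height=_fmt(font), fill=shade, stroke="black")
        _text(g, font + 6, y + font - 2, entry.label, anchor="start",
              size=font)
        row += 1
    return g


def render_legend(key_table, palette: ShadePalette | None = None,
                  font_size: float = 11.0) -> str:
    """Stand-alone SVG fragment: one row per checked key, swatch coloured
    with its shade; unchecked keys absent."""
    palette = palette or ShadePalette()
    g = _legend_group(key_table, palette, font_size)
    g.set("xmlns", "http://www.w3.org/2000/svg")
    return ET.tostring(g, encoding="unicode")


# ---------------------------------------------------------------------------
# document


def render_svg(layout: LayoutResult, p: Pedigree,
               opts: RenderOptions | None = None) -> str:
    """Render a computed layout of ``p`` as an SVG 1.1 document."""
    opts = opts or RenderOptions()
    for iid in layout.positions:
        if iid not in p.individuals:
            raise RenderError(f"layout references unknown individual {iid!r}")
    for iid in p.individuals:
        if iid not in layout.positions:
            raise RenderError(f"individual {iid!r} missing from the layout")

    sc = opts.scale
    font = opts.font_size
    palette = ShadePalette(base_color=opts.base_key_color)
    legend_rows = sum(1 for e in p.key_table.entries if e.checked)
    legend_w = 180.0 if (opts.include_legend and legend_rows) else 0.0
    width = layout.canvas[0] * sc + legend_w
    height = max(layout.canvas[1] * sc,
                 legend_rows * (font + 8) + 40 if legend_w else 0)

    root = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _fmt(width),
        "height": _fmt(height),
        "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
    })
    _el(root, "rect", x="0", y="0", width=_fmt(width), height=_fmt(height),
        fill="white")

    lines_g = _el(root, "g", id="lines")
    for ln in layout.lines:
        pts = [(x * sc, y * sc) for x, y in ln.points]
        style = _LINE_KIND_STYLE.get(ln.kind, {})
        for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
            seg = _line(lines_g, x1, y1, x2, y2, **style)
            seg.set("class", ln.kind)

    # generation labels on the left margin
    labels_g = _el(root, "g", id="generation-labels")
    for g, y in sorted(layout.row_y.items()):
        _text(labels_g, 10, y * sc + font * 0.35, roman_label(p, g),
              size=font + 2)

    glyphs_g = _el(root, "g", id="individuals")
    for iid, (x, y) in layout.positions.items():
        ind = p.individuals[iid]
        spec = symbol_for(ind, p.key_table, palette)
        below = _glyph(glyphs_g, iid, spec, x * sc, y * sc,
                       layout.config.symbol_size * sc, palette, font)
        ty = below + font + 2
        if ind.number:
            _text(glyphs_g, x * sc, ty, str(ind.number), size=font)
            ty += font + 2
        if opts.show_names and ind.name:
            nt = _text(glyphs_g, x * sc, ty, ind.name, size=font)
            nt.set("class", "name")
            ty += font + 2
        for entry in spec.below_text:
            _text(glyphs_g, x * sc, ty, entry, size=font - 1)
            ty += font + 1

    # remarks / metadata block in the top-right corner
    meta = p.metadata
    remark_lines = [s for s in (
        meta.family_names and f"Family: {meta.family_names}",
        meta.paternal_ancestry and f"Paternal ancestry: {meta.paternal_ancestry}",
        meta.maternal_ancestry and f"Maternal ancestry: {meta.maternal_ancestry}",
        meta.date_of_intake and f"Date of intake: {meta.date_of_intake.isoformat()}",
        meta.historian and f"Historian: {meta.historian}",
        meta.reason_for_pedigree and f"Reason: {meta.reason_for_pedigree}",
        meta.remarks and f"Remarks: {meta.remarks}",
    ) if s]
    if remark_lines:
        rg = _el(root, "g", id="remarks")
        for i, s in enumerate(remark_lines):
            _text(rg, width - 8, 16 + i * (font + 3), s, anchor="end",
                  size=font - 1)

    if legend_w:
        lg = _legend_group(p.key_table, palette, font)
        lg.set("transform",
               f"translate({_fmt(layout.canvas[0] * sc + 10)},"
               f"{_fmt(16 + len(remark_lines) * (font + 3) + 10)})")
        root.append(lg)

    if p.comments:
        cg = _el(root, "g", id="comments")
        for c in p.comments:
            if isinstance(c.anchor, str):
                x, y = layout.positions[c.anchor]
                cx, cy = x * sc + layout.config.symbol_size * sc, y * sc - 10
            else:
                cx, cy = c.anchor[0] * sc, c.anchor[1] * sc
            t = _text(cg, cx, cy, c.text, anchor="start", size=font - 1)
            t.set("class", "comment")

    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode") + "\n")
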