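"""Deterministic pedigree chart layout.

Coordinates are abstract chart units with the origin at the top left and y
growing downward; renderers apply their own scale.  Each occupied generation
becomes one row.  Within a row, individuals are ordered left to right by the
builder's slot ordering (husband's branch left of the wife's branch), with
union partners kept horizontally adjacent.  X positions are assigned bottom
row first, then each upper row is centered over its children where spacing
allows (bottom-up sibship packing with a left-to-right sweep).

Line routing: the relationship line runs between adjacent partners at symbol
mid-height; a vertical drop descends from its midpoint to the horizontal
sibship bar, and each child hangs from the bar by a vertical descent line.
Twin lines converge on a shared apex on the sibship bar (diagonal, typed
``twin``), with a ``twin_bar`` crossbar for monozygotic groups.  Crossing
lines are permitted (consanguinity loops need them); symbols never overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .model import Adoption, Pedigree, Zygosity, occupied_levels


@dataclass(frozen=True)
class LayoutConfig:
    symbol_size: float = 30.0
    h_gap: float = 30.0
    v_gap: float = 50.0
    twin_apex_height: float = 12.0
    margin: float = 30.0

    def __post_init__(self) -> None:
        for name in ("symbol_size", "h_gap", "v_gap", "twin_apex_height",
                     "margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h_gap < self.symbol_size:
            raise ValueError("h_gap must be at least symbol_size")


@dataclass(frozen=True)
class Line:
    kind: str  # relationship|descent|sibship|twin|twin_bar|adoption_dashed|
    #           childless|infertility
    points: tuple[tuple[float, float], ...]
    ref: str = ""  # owning union/sibship id, for inspection


@dataclass
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    lines: list[Line]
    bounding_boxes: dict[str, tuple[float, float, float, float]]
    canvas: tuple[float, float]
    rows: dict[int, list[str]] = field(default_factory=dict)
    row_y: dict[int, float] = field(default_factory=dict)
    config: LayoutConfig = field(default_factory=LayoutConfig)


# ---------------------------------------------------------------------------
# ordering


def _sort_key(p: Pedigree):
    insertion = {iid: n for n, iid in enumerate(p.individuals)}

    def key(iid: str):
        return (p.individuals[iid].order_key, insertion[iid], iid)

    return key


def generation_blocks(p: Pedigree) -> dict[int, list[list[str]]]:
    """Per generation, ordered partner-adjacency blocks (marriage chains)."""
    key = _sort_key(p)
    out: dict[int, list[list[str]]] = {}
    for g in occupied_levels(p):
        members = {i.id for i in p.individuals.values() if i.generation == g}
        adj: dict[str, set[str]] = defaultdict(set)
        for u in p.unions.values():
            a, b = u.partners
            if a in members and b in members and a != b:
                adj[a].add(b)
                adj[b].add(a)
        blocks: list[list[str]] = []
        visited: set[str] = set()
        for m in sorted(members, key=key):
            if m in visited:
                continue
            if m not in adj:
                visited.add(m)
                blocks.append([m])
                continue
            # collect the connected component, then order it as a path
            comp = {m}
            frontier = [m]
            while frontier:
                cur = frontier.pop()
                for nxt in adj[cur]:
                    if nxt not in comp:
                        comp.add(nxt)
                        frontier.append(nxt)
            visited |= comp
            ends = [n for n in comp if len(adj[n] & comp) <= 1]
            start = min(ends or comp, key=key)
            chain = [start]
            seen = {start}
            cur = start
            while True:
                nxts = sorted((n for n in adj[cur] & comp if n not in seen),
                              key=key)
                if not nxts:
                    break
                cur = nxts[0]
                chain.append(cur)
                seen.add(cur)
            # branching/cyclic leftovers (hand-built graphs): stable append
            chain.extend(sorted(comp - seen, key=key))
            blocks.append(chain)
        blocks.sort(key=lambda b: min(key(x) for x in b))
        out[g] = blocks
    return out


def generation_orders(p: Pedigree) -> dict[int, list[str]]:
    """Left-to-right individual order per occupied generation level."""
    return {g: [x for b in blocks for x in b]
            for g, blocks in generation_blocks(p).items()}


# ---------------------------------------------------------------------------
# placement


def _row_positions(p: Pedigree, cfg: LayoutConfig) -> tuple[
        dict[str, tuple[float, float]], dict[int, float], dict[int, list[str]]]:
    levels = occupied_levels(p)
    pitch_y = cfg.symbol_size + cfg.v_gap
    unit = cfg.symbol_size + cfg.h_gap
    row_y = {g: cfg.margin + cfg.v_gap + cfg.symbol_size / 2 + r * pitch_y
             for r, g in enumerate(levels)}
    blocks = generation_blocks(p)
    rows = {g: [x for b in bs for x in b] for g, bs in blocks.items()}
    pos: dict[str, tuple[float, float]] = {}

    def children_of_block(block: list[str]) -> list[str]:
        kids: list[str] = []
        in_block = set(block)
        for u in p.unions.values():
            if u.partner_a in in_block or u.partner_b in in_block:
                s = p.sibship_of_union(u.id)
                if s:
                    kids.extend(c for c in s.children if c in pos)
        return kids

    x0 = cfg.margin + cfg.symbol_size / 2
    for g in reversed(levels):
        y = row_y[g]
        if not pos:  # bottom occupied row: sequential packing
            for i, iid in enumerate(rows[g]):
                pos[iid] = (x0 + i * unit, y)
            continue
        cursor = x0
        for block in blocks[g]:
            width = (len(block) - 1) * unit
            kids = children_of_block(block)
            if kids:
                center = sum(pos[k][0] for k in kids) / len(kids)
                start = max(cursor, center - width / 2)
            else:
                start = cursor
            for i, iid in enumerate(block):
                pos[iid] = (start + i * unit, y)
            cursor = start + width + unit
    return pos, row_y, rows


def _union_lines(p: Pedigree, cfg: LayoutConfig,
                 pos: dict[str, tuple[float, float]]) -> list[Line]:
    from .symbols import union_line_style  # late import; symbols uses model only

    s = cfg.symbol_size
    lines: list[Line] = []
    order = {iid: i for i, iid in enumerate(p.individuals)}
    for u in sorted(p.unions.values(), key=lambda u: order[u.partner_a]):
        (xa, ya), (xb, yb) = pos[u.partner_a], pos[u.partner_b]
        if ya != yb:
            # cross-row partnership (not produced by the builder): direct line
            lines.append(Line("relationship", ((xa, ya), (xb, yb)), u.id))
            continue
        left, right = sorted((xa, xb))
        x1, x2 = left + s / 2, right - s / 2
        style = union_line_style(u)
        if style.kind == "double":
            for dy in (-2.0, 2.0):
                lines.append(Line("relationship",
                                  ((x1, ya + dy), (x2, ya + dy)), u.id))
        else:
            lines.append(Line("relationship", ((x1, ya), (x2, ya)), u.id))
        if style.double_slash:
            frac = style.custody_break_offset or 0.5
            # offset is measured from partner_a's side
            bx = (xa + (xb - xa) * frac if xa <= xb
                  else xa - (xa - xb) * frac)
            bx = min(max(bx, x1 + 5), x2 - 5)
            for dx in (-3.0, 3.0):
                lines.append(Line("relationship",
                                  ((bx + dx - 3, ya + 6), (bx + dx + 3, ya - 6)),
                                  u.id))
        # childless markers: a short drop ending in one (by choice) or two
        # (infertility) crossbars
        if u.no_children_by_choice or u.infertility:
            mx = (xa + xb) / 2
            drop = ya + s / 2 + cfg.v_gap / 4
            lines.append(Line("descent", ((mx, ya), (mx, drop)), u.id))
            kind = "infertility" if u.infertility else "childless"
            bars = (0.0, 5.0) if u.infertility else (0.0,)
            for off in bars:
                lines.append(Line(kind, ((mx - 8, drop + off),
                                         (mx + 8, drop + off)), u.id))
    return lines


def _sibship_lines(p: Pedigree, cfg: LayoutConfig,
                   pos: dict[str, tuple[float, float]]) -> list[Line]:
    s = cfg.symbol_size
    lines: list[Line] = []
    for sib in p.sibships.values():
        if not sib.children:
            continue
        child_y = pos[sib.children[0]][1]
        bar_y = child_y - s / 2 - cfg.v_gap / 2
        twin_members = {m for tg in sib.twin_groups for m in tg.members}
        attach_xs: list[float] = []

        # per-child hangers
        for cid in sib.children:
            if cid in twin_members:
                continue
            cx, cy = pos[cid]
            kind = ("adoption_dashed"
                    if p.individuals[cid].adoption == Adoption.ADOPTED_IN
                    else "descent")
            lines.append(Line(kind, ((cx, bar_y), (cx, cy - s / 2)), sib.id))
            attach_xs.append(cx)

        for tg in sib.twin_groups:
            xs = sorted(pos[m][0] for m in tg.members)
            apex = sum(xs) / len(xs)
            attach_xs.append(apex)
            tips = []
            for m in tg.members:
                cx, cy = pos[m]
                top = (cx, cy - s / 2)
                lines.append(Line("twin", ((apex, bar_y), top), sib.id))
                # midpoint of the twin line, for the monozygotic crossbar
                tips.append(((apex + cx) / 2, (bar_y + cy - s / 2) / 2))
            if tg.zygosity == Zygosity.MONOZYGOTIC and len(tips) >= 2:
                lines.append(Line("twin_bar", (tips[0], tips[-1]), sib.id))

        if sib.union_id is not None:
            u = p.unions[sib.union_id]
            mx = (pos[u.partner_a][0] + pos[u.partner_b][0]) / 2
            my = pos[u.partner_a][1]
            lines.append(Line("descent", ((mx, my), (mx, bar_y)), sib.id))
            attach_xs.append(mx)
        lines.append(Line("sibship",
                          ((min(attach_xs), bar_y), (max(attach_xs), bar_y)),
                          sib.id))
    return lines


def compute_layout(p: Pedigree, cfg: Optional[LayoutConfig] = None) -> LayoutResult:
    """Assign chart coordinates and routed lines; deterministic and pure."""
    cfg = cfg or LayoutConfig()
    pos, row_y, rows = _row_positions(p, cfg)
    s = cfg.symbol_size
    boxes = {iid: (x - s / 2, y - s / 2, x + s / 2, y + s / 2)
             for iid, (x, y) in pos.items()}
    lines = _union_lines(p, cfg, pos) + _sibship_lines(p, cfg, pos)
    if pos:
        width = max(x for x, _ in pos.values()) + s / 2 + cfg.margin
        height = max(y for _, y in pos.values()) + s / 2 + cfg.v_gap + cfg.margin
    else:
        width = height = 2 * cfg.margin
    return LayoutResult(positions=pos, lines=lines, bounding_boxes=boxes,
                        canvas=(width, height), rows=rows, row_y=row_y,
                        config=cfg)


def overlap_audit(layout: LayoutResult) -> list[tuple[str, str]]:
    """Exhaustive pairwise bounding-box intersection check.

    Returns each colliding pair once, in deterministic order; empty on any
    ``compute_layout`` output.
    """
    items = sorted(layout.bounding_boxes.items())
    hits: list[tuple[str, str]] = []
    for i, (ida, a) in enumerate(items):
        for idb, b in items[i + 1:]:
            if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                hits.append((ida, idb))
    return hits
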