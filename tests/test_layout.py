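"""Chart geometry: rows, adjacency, line routing, overlap audit."""

import warnings

import pytest

from ftree.builder import OverlayWarning, build_pedigree
from ftree.fixtures import random_questionnaire, scenario_questionnaire
from ftree.layout import LayoutConfig, compute_layout, overlap_audit
from ftree.model import Sex
from ftree.questionnaire import PersonRecord, Questionnaire


def build(q):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OverlayWarning)
        return build_pedigree(q)


def couple_children_q(n):
    q = Questionnaire(client_has_child=True)
    q.put(PersonRecord(slot_id="client", sex=Sex.MALE))
    q.put(PersonRecord(slot_id="spouse", sex=Sex.FEMALE))
    for k in range(1, n + 1):
        q.put(PersonRecord(slot_id="child", index=k, sex=Sex.MALE))
    return q


class TestConfig:
    def test_positive_dimensions_enforced(self):
        with pytest.raises(ValueError):
            LayoutConfig(symbol_size=0)
        with pytest.raises(ValueError):
            LayoutConfig(h_gap=10, symbol_size=30)


class TestGeometry:
    def test_rows_increase_downward(self, d_pedigree):
        lay = compute_layout(d_pedigree)
        ys = [lay.row_y[g] for g in sorted(lay.row_y)]
        assert ys == sorted(ys)
        for g, ids in lay.rows.items():
            assert {lay.positions[i][1] for i in ids} == {lay.row_y[g]}

    def test_children_centered_under_union_midpoint(self):
        p = build(couple_children_q(2))
        lay = compute_layout(p)
        u = next(iter(p.unions.values()))
        mid = (lay.positions[u.partner_a][0] + lay.positions[u.partner_b][0]) / 2
        s = p.sibship_of_union(u.id)
        kids = [lay.positions[c][0] for c in s.children]
        assert mid == pytest.approx(sum(kids) / len(kids))

    def test_partners_horizontally_adjacent(self, ultimate_pedigree):
        lay = compute_layout(ultimate_pedigree)
        unit = lay.config.symbol_size + lay.config.h_gap
        for u in ultimate_pedigree.unions.values():
            (xa, ya), (xb, yb) = (lay.positions[u.partner_a],
                                  lay.positions[u.partner_b])
            assert ya == yb
            assert abs(xa - xb) == pytest.approx(unit)
            # no non-partner symbol between the couple
            lo, hi = sorted((xa, xb))
            between = [i for i, (x, y) in lay.positions.items()
                       if y == ya and lo < x < hi and
                       i not in u.partners]
            assert between == []

    def test_monozygotic_twins_share_apex_with_bar(self):
        q = couple_children_q(0)
        for k in (1, 2):
            q.put(PersonRecord(slot_id="child", index=k, sex=Sex.MALE,
                               multiple_gestation_id=1, monozygotic=True))
        lay = compute_layout(build(q))
        twin = [ln for ln in lay.lines if ln.kind == "twin"]
        assert len(twin) == 2
        assert len({ln.points[0] for ln in twin}) == 1  # shared apex
        assert sum(1 for ln in lay.lines if ln.kind == "twin_bar") == 1

    def test_descent_lines_vertical_at_attachment(self, ultimate_pedigree):
        lay = compute_layout(ultimate_pedigree)
        for ln in lay.lines:
            if ln.kind in ("descent", "adoption_dashed"):
                (x1, _), (x2, _) = ln.points
                assert x1 == pytest.approx(x2)

    def test_sibship_lines_meet_relationship_drop(self, d_pedigree):
        lay = compute_layout(d_pedigree)
        bars = {ln.ref: ln for ln in lay.lines if ln.kind == "sibship"}
        for s in d_pedigree.sibships.values():
            if not s.children or s.union_id is None:
                continue
            u = d_pedigree.unions[s.union_id]
            mid = (lay.positions[u.partner_a][0] +
                   lay.positions[u.partner_b][0]) / 2
            (x1, _), (x2, _) = bars[s.id].points
            assert x1 <= mid <= x2

    def test_consanguineous_double_line_avoids_symbols(self, p_pedigree):
        lay = compute_layout(p_pedigree)
        rel = [ln for ln in lay.lines if ln.kind == "relationship"]
        # brute-force segment-box intersection: no relationship segment may
        # cross a symbol box other than its endpoints' own boxes
        for ln in rel:
            (x1, y1), (x2, y2) = ln.points
            for iid, (bx1, by1, bx2, by2) in lay.bounding_boxes.items():
                if min(x1, x2) < bx2 and bx1 < max(x1, x2) and \
                        min(y1, y2) < by2 and by1 < max(y1, y2):
                    # segment overlaps the box area horizontally/vertically;
                    # tolerate only its own partners' boxes
                    u = p_pedigree.unions[ln.ref]
                    assert iid in u.partners


class TestAudit:
    def test_compute_layout_output_is_clean(self, ultimate_pedigree):
        assert overlap_audit(compute_layout(ultimate_pedigree)) == []

    def test_hand_built_overlap_reported_once(self, d_pedigree):
        lay = compute_layout(d_pedigree)
        ids = list(lay.bounding_boxes)
        lay.bounding_boxes[ids[1]] = lay.bounding_boxes[ids[0]]
        hits = overlap_audit(lay)
        pair = tuple(sorted((ids[0], ids[1])))
        assert hits.count(pair) == 1
        assert (pair[1], pair[0]) not in hits


class TestProperties:
    def test_idempotent(self, p_pedigree):
        a = compute_layout(p_pedigree)
        b = compute_layout(p_pedigree)
        assert a.positions == b.positions
        assert a.lines == b.lines
        assert a.canvas == b.canvas

    def test_adding_a_sibling_never_shrinks_canvas(self):
        widths = [compute_layout(build(couple_children_q(n))).canvas[0]
                  for n in range(1, 7)]
        assert widths == sorted(widths)

    def test_random_questionnaires_have_clean_layouts(self):
        for seed in range(150):
            lay = compute_layout(build(random_questionnaire(seed)))
            assert overlap_audit(lay) == [], f"seed {seed}"
            for ln in lay.lines:
                if ln.kind in ("descent", "adoption_dashed"):
                    assert ln.points[0][0] == pytest.approx(ln.points[1][0])

    @pytest.mark.parametrize("name", ["D", "P", "VHL", "ultimate", "minimal"])
    def test_scenarios_have_clean_layouts(self, name):
        lay = compute_layout(build(scenario_questionnaire(name)))
        assert overlap_audit(lay) == []
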