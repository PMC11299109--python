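import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cohortviz import (DataTable, GenomeAssembly, LabelCandidate, build_scene,
                       export, export_svg, parse_spec, place_labels,
                       resolve_inheritance)
from cohortviz.scene import SceneError


def leaf_spec(mark="rect", encoding=None, values=(), transform=None):
    doc = {"data": {"values": list(values)}, "mark": mark,
           "encoding": encoding or {}}
    if transform:
        doc["transform"] = transform
    return resolve_inheritance(parse_spec(doc))


def test_single_rect_geometry_composes_scale_arithmetic(toy_asm):
    # one segment on chromosome A of a 175 bp toy genome, 175 px viewport:
    # pixel coordinates must equal the hand-computed affine map of the
    # linearized locus (identity here, for legibility)
    spec = leaf_spec(
        values=[{"chrom": "A", "start": 10, "end": 20}],
        encoding={"x": {"field": "start", "type": "locus"},
                  "x2": {"field": "end", "type": "locus"}})
    scene = build_scene(spec, {}, (175, 50), assembly=toy_asm)
    assert len(scene.primitives) == 1
    rect = scene.primitives[0]
    assert (rect.kind, rect.x, rect.x2) == ("rect", 10.0, 20.0)
    assert (rect.y, rect.y2) == (0.0, 50.0)  # no y channel: full height


def test_empty_table_gives_empty_scene():
    spec = leaf_spec(values=[], encoding={"x": {"field": "p", "type": "quantitative"}})
    assert build_scene(spec, {}, (100, 100)).primitives == []


def test_layer_counts_and_order():
    doc = {
        "data": {"values": [{"p": i} for i in range(3)]},
        "encoding": {"x": {"field": "p", "type": "quantitative"}},
        "layer": [
            {"name": "a", "mark": "point"},
            {"name": "b", "mark": "rule",
             "data": {"values": [{"p": 0}, {"p": 1}]}},
        ],
    }
    scene = build_scene(resolve_inheritance(parse_spec(doc)), {}, (100, 100))
    kinds = [p.kind for p in scene.primitives]
    assert kinds == ["point"] * 3 + ["rule"] * 2  # n + m, parent-first order
    assert [p.z for p in scene.primitives] == list(range(5))


def test_vconcat_stacks_regions():
    doc = {
        "data": {"values": [{"p": 1}]},
        "encoding": {"x": {"field": "p", "type": "quantitative"}},
        "vconcat": [{"mark": "rect", "height": 30}, {"mark": "rect"}],
    }
    scene = build_scene(resolve_inheritance(parse_spec(doc)), {}, (100, 100))
    top, bottom = scene.primitives
    assert (top.y, top.y2) == (0.0, 30.0)
    assert (bottom.y, bottom.y2) == (30.0, 100.0)


def test_missing_text_rows_skipped():
    spec = leaf_spec(
        mark="text",
        values=[{"p": 1, "t": "hi"}, {"p": 2, "t": None}],
        encoding={"x": {"field": "p", "type": "quantitative"},
                  "text": {"field": "t", "type": "nominal"}})
    scene = build_scene(spec, {}, (100, 100))
    assert [p.text for p in scene.primitives] == ["hi"]


def test_unknown_column_names_leaf_and_column():
    spec = leaf_spec(values=[{"p": 1}],
                     encoding={"x": {"field": "nope", "type": "quantitative"}})
    with pytest.raises(SceneError, match="nope"):
        build_scene(spec, {}, (100, 100))


def test_facet_by_sample_assigns_bands():
    spec = leaf_spec(
        values=[{"s": "s1", "p": 1}, {"s": "s2", "p": 1}],
        encoding={"x": {"field": "p", "type": "quantitative"},
                  "sample": {"field": "s", "type": "nominal"}})
    scene = build_scene(spec, {}, (100, 100))
    rows = sorted((p.y, p.y2) for p in scene.primitives)
    assert rows == [(0.0, 50.0), (50.0, 100.0)]  # equal heights per sample


# ---------------------------------------------------------------------------
# Label placement


def cand(text, priority, lo, hi):
    return LabelCandidate(text, priority, (lo, hi))


def test_priority_wins_on_overlap():
    a, b = cand("imp", 1, 0, 10), cand("less", 2, 5, 15)
    assert place_labels([b, a], min_gap=0) == [a]


def test_disjoint_both_kept():
    a, b = cand("a", 1, 0, 10), cand("b", 2, 20, 30)
    assert place_labels([a, b], min_gap=2) == [a, b]


def test_third_disjoint_candidate_survives():
    a = cand("a", 1, 0, 10)
    b = cand("b", 2, 5, 15)   # overlaps a -> dropped
    c = cand("c", 3, 20, 30)  # overlaps neither -> kept
    assert place_labels([a, b, c], min_gap=0) == [a, c]


def greedy_oracle(candidates, min_gap):
    """Independent check via per-pixel occupancy on a discretized axis.

    Kept labels occupy their own extent; an incoming candidate is tested with
    its extent padded by the gap, mirroring the placement rule literally.
    """
    scale = 10  # resolve tenths of a pixel
    taken = set()
    kept = set()
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].priority, candidates[i].extent[0]))
    for i in order:
        lo = int((candidates[i].extent[0] - min_gap) * scale)
        hi = int((candidates[i].extent[1] + min_gap) * scale)
        if not (set(range(lo, hi)) & taken):
            kept.add(i)
            taken |= set(range(int(candidates[i].extent[0] * scale),
                               int(candidates[i].extent[1] * scale)))
    return [candidates[i] for i in sorted(kept)]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 90), st.integers(2, 30)),
                max_size=12))
def test_place_labels_matches_occupancy_oracle(raw):
    candidates = [cand(f"g{i}", pr, lo, lo + ln)
                  for i, (pr, lo, ln) in enumerate(raw)]
    assert place_labels(candidates, min_gap=1) == greedy_oracle(candidates, 1)


def test_place_labels_monotone_under_unkept_removal():
    candidates = [cand("a", 1, 0, 10), cand("b", 2, 5, 15), cand("c", 3, 12, 22),
                  cand("d", 4, 30, 40)]
    kept = place_labels(candidates, min_gap=0)
    for drop in candidates:
        if drop in kept:
            continue
        reduced = [c for c in candidates if c is not drop]
        assert place_labels(reduced, min_gap=0) == kept


# ---------------------------------------------------------------------------
# Export


def test_svg_export_is_byte_stable(tmp_path):
    spec = leaf_spec(values=[{"p": 3}],
                     encoding={"x": {"field": "p", "type": "quantitative"}})
    scene = build_scene(spec, {}, (100, 50))
    scene2 = build_scene(spec, {}, (100, 50))
    assert export_svg(scene) == export_svg(scene2)
    svg = export_svg(scene)
    assert svg.count("<rect") == 1
    empty = export_svg(build_scene(leaf_spec(values=[], encoding={}), {}, (40, 20)))
    assert 'width="40"' in empty and "<rect" not in empty


def test_png_matches_svg_presence(tmp_path):
    spec = leaf_spec(values=[{"p": 3}],
                     encoding={"x": {"field": "p", "type": "quantitative"}})
    scene = build_scene(spec, {}, (100, 50))
    export(scene, "svg", tmp_path / "s.svg")
    export(scene, "png", tmp_path / "s.png")
    assert (tmp_path / "s.svg").stat().st_size > 0
    assert (tmp_path / "s.png").read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"
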