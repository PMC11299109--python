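import json

import pandas as pd
import pytest

from cohortviz import (Action, Bookmark, CohortData, History, LocusProbe,
                       apply_action, initial_state, parse_action, replay)
from cohortviz.collection import CollectionError


@pytest.fixture()
def data():
    attrs = pd.DataFrame({
        "sample": ["p1_a", "p1_b", "p2_a", "p3_a", "p3_b", "p4_a"],
        "patient": ["p1", "p1", "p2", "p3", "p3", "p4"],
        "purity": [0.8, 0.3, 0.1, 0.6, 0.7, 0.5],
        "ploidy": [3.4, 3.3, 2.0, 2.0, 2.1, 2.6],
        "stage": ["III", "III", "IV", "III", "IV", "IV"],
    }).set_index("sample", drop=False)
    segments = pd.DataFrame({
        "sample": ["p1_a", "p2_a", "p3_b", "p4_a"],
        "chrom": ["chr19"] * 4,
        "start": [0] * 4,
        "end": [1000] * 4,
        "log2R": [2.0, 0.0, -0.5, 1.0],
        "baf": [0.1, 0.5, 0.2, 0.3],
        "loh": [0.8, 0.0, 0.6, 0.4],
    })
    return CohortData(attrs, segments)


@pytest.fixture()
def state(data):
    return initial_state(data.attributes["sample"])


def test_filter_quant_drops_and_preserves_order(state, data):
    out = apply_action(state, Action("filterQuant", source="purity",
                                     op=">=", threshold=0.5), data)
    assert out.samples == ("p1_a", "p3_a", "p3_b", "p4_a")
    assert state.samples != out.samples  # old state untouched


def test_sort_is_stable(state, data):
    once = apply_action(state, Action("sortBy", source="purity", descending=True), data)
    twice = apply_action(once, Action("sortBy", source="purity", descending=True), data)
    assert once == twice


def test_retain_first_of_each_identity_on_singletons(data):
    solo = initial_state(["p2_a", "p4_a"])
    out = apply_action(solo, Action("retainFirstOfEach", attr="patient"), data)
    assert out == solo


def test_best_sample_per_patient_composition(state, data):
    """Highest purity per patient = sort desc + retain first."""
    s = apply_action(state, Action("sortBy", source="purity", descending=True), data)
    s = apply_action(s, Action("retainFirstOfEach", attr="patient"), data)
    assert set(s.samples) == {"p1_a", "p2_a", "p3_b", "p4_a"}


def test_group_by_threshold_strict_upper_and_partition(state, data):
    out = apply_action(state, Action("groupByThreshold", source="ploidy",
                                     threshold=2.2), data)
    upper, lower = out.groups
    assert upper.labels == ("> 2.2",)
    assert set(upper.samples) == {"p1_a", "p1_b", "p4_a"}
    assert set(upper.samples) | set(lower.samples) == set(state.samples)
    assert not set(upper.samples) & set(lower.samples)


def test_group_by_category_nests_inside_existing_groups(state, data):
    s = apply_action(state, Action("groupByThreshold", source="ploidy",
                                   threshold=2.2), data)
    s = apply_action(s, Action("groupByCategory", attr="stage"), data)
    assert all(len(g.labels) == 2 for g in s.groups)


def test_locus_probe_reads_covering_segment(state, data):
    probe = LocusProbe("chr19", 500, "log2R")
    assert data.value_of("p1_a", probe) == 2.0
    assert data.value_of("p1_b", probe) is None  # no covering segment
    sorted_state = apply_action(state, Action("sortBy", source=probe,
                                              descending=True), data)
    # missing probe values sort last
    assert sorted_state.samples[:3] == ("p1_a", "p4_a", "p2_a")
    assert set(sorted_state.samples[-2:]) >= {"p1_b"}


def test_stricter_filter_composition(state, data):
    loose_then_strict = apply_action(
        apply_action(state, Action("filterQuant", source="purity",
                                   op=">=", threshold=0.3), data),
        Action("filterQuant", source="purity", op=">=", threshold=0.6), data)
    strict = apply_action(state, Action("filterQuant", source="purity",
                                        op=">=", threshold=0.6), data)
    assert loose_then_strict == strict


def test_unknown_attribute_and_bad_probe(state, data):
    with pytest.raises(CollectionError, match="unknown attribute"):
        apply_action(state, Action("filterQuant", source="nope",
                                   op=">", threshold=0), data)
    with pytest.raises(CollectionError, match="kind"):
        LocusProbe("chr19", 0, "vaf")


def test_undo_redo(state, data):
    h = History(state, data)
    a = Action("filterQuant", source="purity", op=">=", threshold=0.5)
    b = Action("sortBy", source="ploidy", descending=False)
    h.apply(a)
    h.apply(b)
    after_ab = h.current
    assert h.undo() == apply_action(state, a, data)
    assert h.redo() == after_ab
    h.undo(); h.undo()
    assert h.current == state
    with pytest.raises(CollectionError, match="undo"):
        h.undo()


def test_apply_after_undo_discards_redo_branch(state, data):
    h = History(state, data)
    h.apply(Action("sortBy", source="purity", descending=True))
    h.undo()
    h.apply(Action("filterQuant", source="purity", op=">", threshold=0.2))
    assert [a.type for a in h.provenance] == ["filterQuant"]
    with pytest.raises(CollectionError, match="redo"):
        h.redo()


def test_replay_reproduces_state(state, data):
    actions = [
        Action("filterQuant", source="purity", op=">=", threshold=0.15),
        Action("sortBy", source="purity", descending=True),
        Action("retainFirstOfEach", attr="patient"),
        Action("groupByThreshold", source="ploidy", threshold=2.2),
    ]
    once = replay(state, actions, data)
    again = replay(state, actions, data)
    assert once == again
    assert json.dumps(once.to_dict()) == json.dumps(again.to_dict())


def test_bookmark_roundtrip():
    actions = (Action("filterQuant", source="purity", op=">=", threshold=0.15),
               Action("sortBy", source=LocusProbe("chr19", 500, "log2R"),
                      descending=True))
    bm = Bookmark(name="wgd-split", actions=actions,
                  notes="## Findings\n*CCNE1*-like peak in upper group\n",
                  scale_domains={"x": (0.0, 3_000_000.0)},
                  view_visibility={"gscore": True, "ssv": False})
    again = Bookmark.from_json(bm.to_json())
    assert again == bm
    assert again.notes == bm.notes  # byte-exact Markdown
    assert Bookmark.from_json(Bookmark(name="empty").to_json()) == Bookmark(name="empty")


def test_bookmark_parse_errors_carry_path():
    with pytest.raises(CollectionError, match=r"\$\.name"):
        Bookmark.from_json("{}")
    with pytest.raises(CollectionError, match=r"\$\.actions\[0\]"):
        Bookmark.from_json(json.dumps({"name": "x", "actions": [{"type": "wat"}]}))
    with pytest.raises(CollectionError, match=r"\$\.scaleDomains"):
        Bookmark.from_json(json.dumps({"name": "x", "scaleDomains": {"x": [1]}}))


def test_action_json_roundtrip():
    for action in (Action("filterCategory", attr="stage", retain=("III",)),
                   Action("groupByThreshold", source="ploidy", threshold=2.2),
                   Action("sortBy", source=LocusProbe("chr19", 1, "loh"),
                          descending=True)):
        assert parse_action(json.loads(json.dumps(action.to_dict()))) == action
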