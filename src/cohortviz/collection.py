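"""Reversible, incremental actions over a faceted sample collection.

The sample axis of a cohort visualization is an ordered, optionally grouped
list of sample ids.  Analysts shape it with small composable actions —
filter by a metadata category or quantity, sort, keep the first sample per
patient, split into groups by category or threshold — where a quantity can be
either a metadata attribute (purity, ploidy, breakpoint count…) or a *locus
probe*: the value (log2R, BAF or LOH) of the sample's copy-number segment
covering a genomic position.

Actions never mutate state; each application returns a new
:class:`CollectionState`.  The ordered action log is the provenance: replaying
it from the initial state reproduces the current state exactly, which is what
makes undo/redo and serialized bookmarks trivial and trustworthy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GenomeAssembly

__all__ = [
    "Group", "CollectionState", "LocusProbe", "Action", "CohortData",
    "History", "Bookmark", "initial_state", "apply_action", "parse_action",
]


class CollectionError(ValueError):
    pass


@dataclass(frozen=True)
class Group:
    """Ordered samples under a (possibly nested) label path."""

    labels: tuple[str, ...]
    samples: tuple[str, ...]


@dataclass(frozen=True)
class CollectionState:
    groups: tuple[Group, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for s in g.samples:
                if s in seen:
                    raise CollectionError(f"sample {s!r} appears in multiple groups")
                seen.add(s)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for g in self.groups for s in g.samples)

    def to_dict(self) -> dict[str, Any]:
        return {"groups": [{"labels": list(g.labels), "samples": list(g.samples)}
                           for g in self.groups]}


def initial_state(sample_ids: Iterable[str]) -> CollectionState:
    """All samples in one unlabeled root group, input order preserved."""
    return CollectionState(groups=(Group((), tuple(sample_ids)),))


# ---------------------------------------------------------------------------
# Data access: metadata attributes and locus probes


@dataclass(frozen=True)
class LocusProbe:
    """A measurement at a genomic position: the covering segment's value."""

    chrom: str
    pos: int
    kind: str  # log2R | baf | loh

    KINDS = ("log2R", "baf", "loh")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise CollectionError(f"unknown probe kind {self.kind!r}; "
                                  f"allowed: {list(self.KINDS)}")


Source = Union[str, LocusProbe]

_PROBE_COLUMNS = {"log2R": "log2R", "baf": "baf", "loh": "loh"}


class CohortData:
    """Read-only access the actions need: per-sample metadata and segments.

    ``attributes`` is indexed by sample id; ``segments`` carries sample,
    chrom, start, end plus the value columns probes may ask for (log2R, baf,
    and/or loh — typically the purified versions, renamed by the caller).
    """

    def __init__(self, attributes: pd.DataFrame,
                 segments: Optional[pd.DataFrame] = None,
                 assembly: Optional[GenomeAssembly] = None):
        self.attributes = attributes
        self.segments = segments
        self.assembly = assembly

    def value_of(self, sample: str, source: Source) -> Any:
        if isinstance(source, LocusProbe):
            return self._probe(sample, source)
        if source not in self.attributes.columns:
            raise CollectionError(f"unknown attribute {source!r}")
        v = self.attributes.at[sample, source]
        return None if pd.isna(v) else v

    def _probe(self, sample: str, probe: LocusProbe) -> Optional[float]:
        if self.segments is None:
            raise CollectionError("no segment table available for locus probes")
        if self.assembly is not None:
            if probe.chrom not in self.assembly:
                raise CollectionError(f"probe chromosome {probe.chrom!r} not in assembly")
            if not 0 <= probe.pos < self.assembly.length_of(probe.chrom):
                raise CollectionError(
                    f"probe position {probe.chrom}:{probe.pos} outside assembly")
        col = _PROBE_COLUMNS[probe.kind]
        if col not in self.segments.columns:
            raise CollectionError(f"segment table lacks column {col!r}")
        seg = self.segments
        hit = seg[(seg["sample"] == sample) & (seg["chrom"] == probe.chrom)
                  & (seg["start"] <= probe.pos) & (probe.pos < seg["end"])]
        if hit.empty:
            return None
        v = hit.iloc[0][col]
        return None if pd.isna(v) else float(v)


# ---------------------------------------------------------------------------
# Actions

_OPS = {">=": lambda a, b: a >= b, "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b, "<": lambda a, b: a < b}


@dataclass(frozen=True)
class Action:
    """One reversible step; JSON-serializable without loss.

    ``type`` is one of filterCategory, filterQuant, sortBy, retainFirstOfEach,
    groupByCategory, groupByThreshold.
    """

    type: str
    attr: Optional[str] = None
    retain: Optional[tuple] = None
    source: Optional[Source] = None
    op: Optional[str] = None
    threshold: Optional[float] = None
    descending: bool = False

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"type": self.type}
        if self.attr is not None:
            out["attr"] = self.attr
        if self.retain is not None:
            out["retain"] = list(self.retain)
        if self.source is not None:
            if isinstance(self.source, LocusProbe):
                out["source"] = {"chrom": self.source.chrom, "pos": self.source.pos,
                                 "kind": self.source.kind}
            else:
                out["source"] = self.source
        if self.op is not None:
            out["op"] = self.op
        if self.threshold is not None:
            out["threshold"] = self.threshold
        if self.type == "sortBy":
            out["descending"] = self.descending
        return out


_ACTION_TYPES = ("filterCategory", "filterQuant", "sortBy", "retainFirstOfEach",
                 "groupByCategory", "groupByThreshold")


def parse_action(obj: Mapping[str, Any]) -> Action:
    atype = obj.get("type")
    if atype not in _ACTION_TYPES:
        raise CollectionError(f"unknown action type {atype!r}; allowed: {list(_ACTION_TYPES)}")
    source: Optional[Source] = obj.get("source")
    if isinstance(source, Mapping):
        source = LocusProbe(source["chrom"], int(source["pos"]), source["kind"])
    retain = obj.get("retain")
    return Action(type=atype, attr=obj.get("attr"),
                  retain=tuple(retain) if retain is not None else None,
                  source=source, op=obj.get("op"),
                  threshold=obj.get("threshold"),
                  descending=bool(obj.get("descending", False)))


def apply_action(state: CollectionState, action: Action,
                 data: CohortData) -> CollectionState:
    """Apply one action, returning a new state; the old one is untouched."""
    if action.type == "filterCategory":
        retain = set(action.retain or ())
        return _filter(state, lambda s: data.value_of(s, _req(action.attr)) in retain)
    if action.type == "filterQuant":
        op = _OPS.get(action.op or "")
        if op is None:
            raise CollectionError(f"unknown comparison {action.op!r}")
        thr = _req(action.threshold)

        def keep(s: str) -> bool:
            v = data.value_of(s, _req(action.source))
            return v is not None and op(float(v), thr)  # missing fails the filter
        return _filter(state, keep)
    if action.type == "sortBy":
        return _sort(state, data, _req(action.source), action.descending)
    if action.type == "retainFirstOfEach":
        return _retain_first(state, data, _req(action.attr))
    if action.type == "groupByCategory":
        return _group_by(state, lambda s: str(data.value_of(s, _req(action.attr))),
                         label_order=None)
    if action.type == "groupByThreshold":
        thr = _req(action.threshold)
        src = _req(action.source)

        def bucket(s: str) -> str:
            v = data.value_of(s, src)
            # strict > forms the upper group; missing goes below
            return f"> {thr:g}" if v is not None and float(v) > thr else f"<= {thr:g}"
        return _group_by(state, bucket, label_order=[f"> {thr:g}", f"<= {thr:g}"])
    raise CollectionError(f"unknown action type {action.type!r}")


def _req(value):
    if value is None:
        raise CollectionError("action is missing a required property")
    return value


def _filter(state: CollectionState, keep) -> CollectionState:
    groups = []
    for g in state.groups:
        kept = tuple(s for s in g.samples if keep(s))
        if kept:  # empty groups are removed
            groups.append(Group(g.labels, kept))
    return CollectionState(tuple(groups))


def _sort_key(v):
    # missing sorts last regardless of direction
    return (v is None, v)


def _sort(state: CollectionState, data: CohortData, source: Source,
          descending: bool) -> CollectionState:
    groups = []
    for g in state.groups:
        values = {s: data.value_of(s, source) for s in g.samples}
        present = [s for s in g.samples if values[s] is not None]
        missing = [s for s in g.samples if values[s] is None]
        ordered = sorted(present, key=lambda s: values[s], reverse=descending)
        groups.append(Group(g.labels, tuple(ordered + missing)))
    return CollectionState(tuple(groups))


def _retain_first(state: CollectionState, data: CohortData, attr: str) -> CollectionState:
    seen: set = set()
    groups = []
    for g in state.groups:
        kept = []
        for s in g.samples:
            key = data.value_of(s, attr)
            if key not in seen:
                seen.add(key)
                kept.append(s)
        if kept:
            groups.append(Group(g.labels, tuple(kept)))
    return CollectionState(tuple(groups))


def _group_by(state: CollectionState, bucket, label_order) -> CollectionState:
    """Split every current group by bucket label; new splits nest inside."""
    groups = []
    for g in state.groups:
        buckets: dict[str, list[str]] = {}
        for s in g.samples:
            buckets.setdefault(bucket(s), []).append(s)
        labels = (label_order and [l for l in label_order if l in buckets]) or \
            sorted(buckets)
        for label in labels:
            groups.append(Group(g.labels + (label,), tuple(buckets[label])))
    return CollectionState(tuple(groups))


# ---------------------------------------------------------------------------
# History (undo/redo) and bookmarks


class History:
    """Action log with an undo pointer; replay is the source of truth."""

    def __init__(self, initial: CollectionState, data: CohortData):
        self._states: list[CollectionState] = [initial]
        self.actions: list[Action] = []
        self._pointer = 0  # number of applied actions currently in effect
        self.data = data

    @property
    def current(self) -> CollectionState:
        return self._states[self._pointer]

    @property
    def provenance(self) -> list[Action]:
        return self.actions[: self._pointer]

    def apply(self, action: Action) -> CollectionState:
        new = apply_action(self.current, action, self.data)
        # applying after an undo discards the redo branch
        del self._states[self._pointer + 1:]
        del self.actions[self._pointer:]
        self._states.append(new)
        self.actions.append(action)
        self._pointer += 1
        return new

    def undo(self) -> CollectionState:
        if self._pointer == 0:
            raise CollectionError("nothing to undo")
        self._pointer -= 1
        return self.current

    def redo(self) -> CollectionState:
        if self._pointer >= len(self.actions):
            raise CollectionError("nothing to redo")
        self._pointer += 1
        return self.current


def replay(initial: CollectionState, actions: Sequence[Action],
           data: CohortData) -> CollectionState:
    """Pure replay of an action log — the provenance contract."""
    state = initial
    for action in actions:
        state = apply_action(state, action, data)
    return state


@dataclass(frozen=True)
class Bookmark:
    """A shareable snapshot: action log + scale domains + view visibility."""

    name: str
    actions: tuple[Action, ...] = ()
    notes: Optional[str] = None  # Markdown, preserved byte-exact
    scale_domains: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    view_visibility: Mapping[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "actions": [a.to_dict() for a in self.actions],
            "scaleDomains": {k: list(v) for k, v in sorted(self.scale_domains.items())},
            "viewVisibility": dict(sorted(self.view_visibility.items())),
        }
        if self.notes is not None:
            doc["notes"] = self.notes
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Bookmark":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CollectionError(f"$: bookmark is not valid JSON: {exc.msg}") from None
        if not isinstance(doc, Mapping):
            raise CollectionError("$: bookmark must be a JSON object")
        if "name" not in doc or not isinstance(doc["name"], str):
            raise CollectionError("$.name: required string")
        actions = []
        for i, a in enumerate(doc.get("actions", [])):
            try:
                actions.append(parse_action(a))
            except (CollectionError, KeyError, TypeError) as exc:
                raise CollectionError(f"$.actions[{i}]: {exc}") from None
        domains = {}
        for key, pair in (doc.get("scaleDomains") or {}).items():
            if (not isinstance(pair, Sequence)) or len(pair) != 2:
                raise CollectionError(f"$.scaleDomains.{key}: expected [lo, hi]")
            domains[key] = (float(pair[0]), float(pair[1]))
        visibility = {}
        for key, flag in (doc.get("viewVisibility") or {}).items():
            if not isinstance(flag, bool):
                raise CollectionError(f"$.viewVisibility.{key}: expected boolean")
            visibility[key] = flag
        return cls(name=doc["name"], actions=tuple(actions),
                   notes=doc.get("notes"), scale_domains=domains,
                   view_visibility=visibility)
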