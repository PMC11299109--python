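"""Parsing and validation of the JSON visualization grammar.

A specification is a tree of views.  Each view may carry a data source, an
ordered transform list and channel encodings, and is either a leaf with a
``mark`` or a composite with ``layer`` (children share the coordinate region)
or ``vconcat`` (children stack vertically).  Data sources and encodings are
inherited downward; a child channel definition overrides the parent's for
that channel only.

The accepted subset is fixed: marks ``rect | point | text | rule``; channels
``x x2 y y2 color opacity size text sample``; field types ``quantitative |
ordinal | nominal | locus``.  Anything outside the subset is a validation
error carrying the JSON path — never a silent ignore.  A JSON-Schema document
describing the subset ships in ``cohortviz/schemas/viewspec.schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

__all__ = ["ViewSpec", "EncodingChannel", "SpecError", "parse_spec",
           "resolve_inheritance", "serialize_spec"]

MARK_TYPES = ("rect", "point", "text", "rule")
CHANNELS = ("x", "x2", "y", "y2", "color", "opacity", "size", "text", "sample")
FIELD_TYPES = ("quantitative", "ordinal", "nominal", "locus")
TRANSFORM_TYPES = ("filter", "formula", "flattenSequence", "coverage", "semanticZoom")
SCALE_KINDS = ("linear", "band", "ordinal-color", "linear-color", "locus")

_VIEW_KEYS = {"data", "transform", "encoding", "mark", "layer", "vconcat",
              "name", "visible", "params", "height"}


class SpecError(ValueError):
    """Validation failure; message always starts with the JSON path."""

    def __init__(self, path: str, message: str):
        self.path = path or "$"
        super().__init__(f"{self.path}: {message}")


@dataclass(frozen=True)
class EncodingChannel:
    channel: str
    field: Optional[str] = None
    value: Any = None
    type: Optional[str] = None
    scale: Optional[Mapping[str, Any]] = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        if self.field is not None:
            out["field"] = self.field
        if self.value is not None:
            out["value"] = self.value
        if self.type is not None:
            out["type"] = self.type
        if self.scale is not None:
            out["scale"] = dict(self.scale)
        return out


@dataclass(frozen=True)
class ViewSpec:
    """One node of the parsed view tree."""

    data: Optional[Mapping[str, Any]] = None
    transform: tuple[Mapping[str, Any], ...] = ()
    encoding: Mapping[str, EncodingChannel] = field(default_factory=dict)
    mark: Optional[str] = None
    layer: tuple["ViewSpec", ...] = ()
    vconcat: tuple["ViewSpec", ...] = ()
    name: Optional[str] = None
    visible: bool = True
    params: Mapping[str, Any] = field(default_factory=dict)
    height: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.mark is not None

    @property
    def children(self) -> tuple["ViewSpec", ...]:
        return self.layer or self.vconcat

    def leaves(self) -> list["ViewSpec"]:
        if self.is_leaf:
            return [self]
        out: list[ViewSpec] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        if self.name is not None:
            out["name"] = self.name
        if self.data is not None:
            out["data"] = dict(self.data)
        if self.transform:
            out["transform"] = [dict(t) for t in self.transform]
        if self.encoding:
            out["encoding"] = {ch: enc.to_dict() for ch, enc in self.encoding.items()}
        if self.mark is not None:
            out["mark"] = self.mark
        if self.layer:
            out["layer"] = [v.to_dict() for v in self.layer]
        if self.vconcat:
            out["vconcat"] = [v.to_dict() for v in self.vconcat]
        if not self.visible:
            out["visible"] = False
        if self.params:
            out["params"] = dict(self.params)
        if self.height is not None:
            out["height"] = self.height
        return out


def parse_spec(document: Union[str, Mapping[str, Any], Path]) -> ViewSpec:
    """Parse JSON text (or an already-decoded mapping) into a validated tree."""
    if isinstance(document, Path):
        document = document.read_text()
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SpecError("$", f"not well-formed JSON: {exc.msg} (line {exc.lineno})")
    return _parse_view(document, "$")


def serialize_spec(spec: ViewSpec) -> str:
    """Canonical JSON form; ``parse_spec(serialize_spec(s))`` is a fixpoint."""
    return json.dumps(spec.to_dict(), indent=2, sort_keys=True)


def _parse_view(node: Any, path: str) -> ViewSpec:
    if not isinstance(node, Mapping):
        raise SpecError(path, f"view must be a JSON object, got {type(node).__name__}")
    unknown = set(node) - _VIEW_KEYS
    if unknown:
        raise SpecError(path, f"unknown propert{'ies' if len(unknown) > 1 else 'y'} "
                              f"{sorted(unknown)}; allowed: {sorted(_VIEW_KEYS)}")
    present = [k for k in ("mark", "layer", "vconcat") if k in node]
    if len(present) != 1:
        raise SpecError(path, "exactly one of mark/layer/vconcat is required, "
                              f"found {present or 'none'}")

    mark = None
    layer: tuple[ViewSpec, ...] = ()
    vconcat: tuple[ViewSpec, ...] = ()
    if "mark" in node:
        mark = node["mark"]
        if mark not in MARK_TYPES:
            raise SpecError(f"{path}.mark",
                            f"unknown mark {mark!r}; allowed marks: {list(MARK_TYPES)}")
    elif "layer" in node:
        layer = _parse_children(node["layer"], f"{path}.layer")
    else:
        vconcat = _parse_children(node["vconcat"], f"{path}.vconcat")

    data = _parse_data(node.get("data"), f"{path}.data")
    transform = _parse_transforms(node.get("transform"), f"{path}.transform")
    encoding = _parse_encoding(node.get("encoding"), f"{path}.encoding")

    if mark == "text" and encoding is not None and "text" not in encoding:
        # validated again after inheritance; reject early only if locally complete
        pass

    visible = node.get("visible", True)
    if not isinstance(visible, bool):
        raise SpecError(f"{path}.visible", "must be a boolean")
    params = node.get("params", {})
    if not isinstance(params, Mapping):
        raise SpecError(f"{path}.params", "must be an object of name → value")
    name = node.get("name")
    if name is not None and not isinstance(name, str):
        raise SpecError(f"{path}.name", "must be a string")
    height = node.get("height")
    if height is not None and (not isinstance(height, (int, float)) or height <= 0):
        raise SpecError(f"{path}.height", "must be a positive number")

    return ViewSpec(data=data, transform=transform, encoding=encoding or {},
                    mark=mark, layer=layer, vconcat=vconcat, name=name,
                    visible=visible, params=dict(params), height=height)


def _parse_children(nodes: Any, path: str) -> tuple[ViewSpec, ...]:
    if not isinstance(nodes, Sequence) or isinstance(nodes, (str, bytes)):
        raise SpecError(path, "must be an array of views")
    if not nodes:
        raise SpecError(path, "must not be empty")
    return tuple(_parse_view(child, f"{path}[{i}]") for i, child in enumerate(nodes))


def _parse_data(node: Any, path: str) -> Optional[Mapping[str, Any]]:
    if node is None:
        return None
    if not isinstance(node, Mapping):
        raise SpecError(path, "must be an object")
    if ("url" in node) == ("values" in node):
        raise SpecError(path, "exactly one of url/values is required")
    allowed = {"url", "values", "format", "oneBased"}
    unknown = set(node) - allowed
    if unknown:
        raise SpecError(path, f"unknown properties {sorted(unknown)}")
    return dict(node)


def _parse_transforms(node: Any, path: str) -> tuple[Mapping[str, Any], ...]:
    if node is None:
        return ()
    if not isinstance(node, Sequence) or isinstance(node, (str, bytes)):
        raise SpecError(path, "must be an array of transform steps")
    steps = []
    for i, step in enumerate(node):
        if not isinstance(step, Mapping) or "type" not in step:
            raise SpecError(f"{path}[{i}]", "transform step must be an object with a type")
        if step["type"] not in TRANSFORM_TYPES:
            raise SpecError(f"{path}[{i}].type",
                            f"unknown transform {step['type']!r}; "
                            f"allowed: {list(TRANSFORM_TYPES)}")
        steps.append(dict(step))
    return tuple(steps)


def _parse_encoding(node: Any, path: str) -> Optional[dict[str, EncodingChannel]]:
    if node is None:
        return None
    if not isinstance(node, Mapping):
        raise SpecError(path, "must be an object of channel → definition")
    out: dict[str, EncodingChannel] = {}
    for channel, definition in node.items():
        cpath = f"{path}.{channel}"
        if channel not in CHANNELS:
            raise SpecError(cpath, f"unknown channel; allowed: {list(CHANNELS)}")
        if not isinstance(definition, Mapping):
            raise SpecError(cpath, "channel definition must be an object")
        if ("field" in definition) == ("value" in definition):
            raise SpecError(cpath, "exactly one of field/value is required")
        ftype = definition.get("type")
        if ftype is not None and ftype not in FIELD_TYPES:
            raise SpecError(f"{cpath}.type",
                            f"unknown type {ftype!r}; allowed: {list(FIELD_TYPES)}")
        if ftype == "locus" and channel not in ("x", "x2", "y", "y2"):
            raise SpecError(cpath, "locus type is only valid on positional channels")
        scale = definition.get("scale")
        if scale is not None:
            if not isinstance(scale, Mapping):
                raise SpecError(f"{cpath}.scale", "must be an object")
            kind = scale.get("kind")
            if kind is not None and kind not in SCALE_KINDS:
                raise SpecError(f"{cpath}.scale.kind",
                                f"unknown scale kind {kind!r}; allowed: {list(SCALE_KINDS)}")
        out[channel] = EncodingChannel(
            channel=channel, field=definition.get("field"),
            value=definition.get("value"), type=ftype,
            scale=dict(scale) if scale is not None else None)
    return out


def resolve_inheritance(spec: ViewSpec) -> ViewSpec:
    """Push data sources and encodings down so every leaf is self-contained.

    Child channel definitions override the parent's per channel; ancestor
    transforms run before the leaf's own; a leaf that ends up with no data
    source anywhere on its path is an error.
    """
    return _resolve(spec, None, {}, (), "$")


def _resolve(view: ViewSpec, data: Optional[Mapping[str, Any]],
             encoding: Mapping[str, EncodingChannel],
             transforms: tuple[Mapping[str, Any], ...], path: str) -> ViewSpec:
    eff_data = view.data if view.data is not None else data
    eff_encoding = dict(encoding)
    eff_encoding.update(view.encoding)
    eff_transforms = transforms + view.transform
    if view.is_leaf:
        if eff_data is None:
            raise SpecError(path, "leaf view has no data source anywhere on its path")
        if view.mark == "text" and "text" not in eff_encoding:
            raise SpecError(path, "text mark requires a text channel")
        for secondary, primary in (("x2", "x"), ("y2", "y")):
            if secondary in eff_encoding and primary not in eff_encoding:
                raise SpecError(f"{path}.encoding.{secondary}",
                                f"{secondary} requires {primary} on the same view")
        return replace(view, data=eff_data, encoding=eff_encoding,
                       transform=eff_transforms)
    kwargs: dict[str, Any] = {}
    key = "layer" if view.layer else "vconcat"
    kwargs[key] = tuple(
        _resolve(child, eff_data, eff_encoding, eff_transforms, f"{path}.{key}[{i}]")
        for i, child in enumerate(view.children))
    return replace(view, **kwargs)
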