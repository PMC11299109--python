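"""Scene construction and static export.

A resolved view tree plus its per-leaf tables is flattened into an ordered
list of drawing primitives (rect/point/text/rule) in a pixel viewport —
deterministically: views in tree order, rows in table order.  The scene list
is the test surface; SVG export is byte-stable string building and PNG
export rasterizes the same primitives through Pillow.

Label placement follows the greedy popularity rule used for gene symbols on
annotation tracks: candidates are processed in ascending priority rank and a
label is shown only if there is still room on the track (no overlap with an
already-placed label, padded by a minimum gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

from .dataflow import DataTable, apply_transforms
from .encoding import Scale, resolve_scale, scale_apply
from .genome import GenomeAssembly, linearize
from .grammar import EncodingChannel, ViewSpec

__all__ = ["Primitive", "Scene", "LabelCandidate", "build_scene",
           "place_labels", "export", "export_svg"]

DEFAULT_FILL = "#4e79a7"
DEFAULT_POINT_SIZE = 4.0
DEFAULT_FONT_SIZE = 10.0


class SceneError(ValueError):
    pass


@dataclass(frozen=True)
class Primitive:
    kind: str  # rect | point | text | rule
    x: float
    y: float
    x2: Optional[float] = None
    y2: Optional[float] = None
    fill: str = DEFAULT_FILL
    opacity: float = 1.0
    size: float = DEFAULT_POINT_SIZE
    text: Optional[str] = None
    z: int = 0

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.x2, self.y2):
            if v is not None and not math.isfinite(v):
                raise SceneError(f"non-finite coordinate in {self.kind} primitive")
        if self.kind == "rect" and (self.x2 is None or self.y2 is None):
            raise SceneError("rect requires x2 and y2")


@dataclass
class Scene:
    width: float
    height: float
    primitives: list[Primitive] = field(default_factory=list)


@dataclass(frozen=True)
class LabelCandidate:
    text: str
    priority: int  # lower rank = more important
    extent: tuple[float, float]  # pixel interval along the track axis

    def __post_init__(self) -> None:
        if not self.extent[0] < self.extent[1]:
            raise SceneError(f"label {self.text!r} has empty extent")


# ---------------------------------------------------------------------------
# Scene building


def build_scene(tree: ViewSpec, tables: Mapping[str, DataTable],
                viewport: tuple[float, float],
                assembly: Optional[GenomeAssembly] = None,
                params: Optional[Mapping[str, Any]] = None,
                run_transforms: bool = True) -> Scene:
    """Flatten a resolved tree into primitives.

    ``tables`` maps leaf names to their input tables (leaves with inline
    ``data.values`` need no entry).  Transforms run here unless the caller
    already did (``run_transforms=False``).
    """
    width, height = viewport
    scene = Scene(width, height)
    _emit_view(tree, tables, (0.0, 0.0, width, height), scene, assembly,
               dict(params or {}), run_transforms, counter=[0])
    return scene


def _emit_view(view: ViewSpec, tables, region, scene, assembly, params,
               run_transforms, counter) -> None:
    if not view.visible:
        return
    merged_params = dict(params)
    merged_params.update(view.params)
    if view.mark is not None:
        _emit_leaf(view, tables, region, scene, assembly, merged_params,
                   run_transforms, counter)
        return
    x0, y0, x1, y1 = region
    if view.layer:
        for child in view.layer:  # layered children share the parent's region
            _emit_view(child, tables, region, scene, assembly, merged_params,
                       run_transforms, counter)
        return
    heights = [c.height for c in view.vconcat]
    fixed = sum(h for h in heights if h is not None)
    n_auto = sum(1 for h in heights if h is None)
    auto = max(0.0, (y1 - y0) - fixed) / n_auto if n_auto else 0.0
    offset = y0
    for child, h in zip(view.vconcat, heights):
        ch = h if h is not None else auto
        _emit_view(child, tables, (x0, offset, x1, offset + ch), scene,
                   assembly, merged_params, run_transforms, counter)
        offset += ch


def _leaf_table(view: ViewSpec, tables, counter) -> DataTable:
    from .dataflow import inline_table, read_table

    name = view.name or f"view_{counter[0]}"
    if name in tables:
        return tables[name]
    data = view.data or {}
    if "values" in data:
        return inline_table(data["values"])
    if "url" in data:
        return read_table(data["url"], data.get("format"),
                          one_based=bool(data.get("oneBased", False)))
    raise SceneError(f"no table provided for leaf {name!r}")


def _emit_leaf(view: ViewSpec, tables, region, scene, assembly, params,
               run_transforms, counter) -> None:
    table = _leaf_table(view, tables, counter)
    counter[0] += 1
    if run_transforms and view.transform:
        table = apply_transforms(table, view.transform, params)
    x0, y0, x1, y1 = region
    scales = _resolve_leaf_scales(view, table, region, assembly)
    rows = table.rows()
    name = view.name or "?"
    for enc in view.encoding.values():
        if enc.field is not None and rows and enc.field not in table.columns:
            raise SceneError(
                f"leaf {name!r}: channel {enc.channel!r} references column "
                f"{enc.field!r} absent after transforms")
    for row in rows:
        prim = _encode_row(view, row, scales, region, len(scene.primitives))
        if prim is not None:
            scene.primitives.append(prim)


def _channel_values(enc: EncodingChannel, table: DataTable) -> list:
    return [v for v in (row.get(enc.field) for row in table.rows()) if v is not None]


def _resolve_leaf_scales(view: ViewSpec, table: DataTable, region,
                         assembly) -> dict[str, Scale]:
    """Infer a concrete scale per channel: explicit spec > data-driven default."""
    x0, y0, x1, y1 = region
    scales: dict[str, Scale] = {}
    for channel, enc in view.encoding.items():
        if enc.field is None or channel == "text":
            continue
        base = channel[0] if channel in ("x2", "y2") else channel
        if base in scales and channel in ("x2", "y2"):
            continue
        if channel == "sample":
            # facet-by-sample: a band scale on y; row order supplied upstream
            scales[channel] = resolve_scale(enc.scale, "band",
                                            domain=_categories(view, channel, table),
                                            range_=(y0, y1))
            continue
        if channel in ("x", "x2"):
            rng = (x0, x1)
        elif channel in ("y", "y2"):
            rng = (y1, y0)  # pixel y grows downward; domain min at bottom
        else:
            rng = None
        ftype = enc.type or "quantitative"
        if ftype == "locus":
            scales[base] = resolve_scale(enc.scale, "locus", range_=rng,
                                         assembly=assembly)
        elif ftype == "quantitative":
            if channel in ("color",):
                scales[base] = resolve_scale(enc.scale, "linear-color",
                                             domain=_quant_domain(view, channel, table))
            elif channel in ("opacity", "size"):
                default_range = (0.0, 1.0) if channel == "opacity" else (1.0, 8.0)
                scales[base] = resolve_scale(enc.scale, "linear",
                                             domain=_quant_domain(view, channel, table),
                                             range_=default_range)
            else:
                scales[base] = resolve_scale(enc.scale, "linear",
                                             domain=_quant_domain(view, channel, table),
                                             range_=rng)
        else:  # ordinal / nominal
            cats = _categories(view, channel, table)
            if channel == "color":
                scales[base] = resolve_scale(enc.scale, "ordinal-color", domain=cats)
            else:
                scales[base] = resolve_scale(enc.scale, "band", domain=cats,
                                             range_=rng)
    return scales


def _quant_domain(view: ViewSpec, channel: str, table: DataTable) -> tuple[float, float]:
    values: list[float] = []
    for ch in (channel, channel + "2"):
        enc = view.encoding.get(ch)
        if enc is not None and enc.field is not None:
            values.extend(float(v) for v in _channel_values(enc, table))
    if not values:
        return (0.0, 1.0)
    lo, hi = min(values), max(values)
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return (lo, hi)


def _categories(view: ViewSpec, channel: str, table: DataTable) -> list:
    enc = view.encoding[channel]
    seen: list = []
    for v in _channel_values(enc, table):
        if v not in seen:
            seen.append(v)  # first-occurrence order, deterministic
    return seen or ["?"]


def _encode_row(view: ViewSpec, row: Mapping[str, Any], scales, region,
                z: int) -> Optional[Primitive]:
    x0, y0, x1, y1 = region

    def channel(name: str, default=None):
        enc = view.encoding.get(name)
        if enc is None:
            return default
        if enc.value is not None:
            return enc.value
        v = row.get(enc.field)
        if v is None:
            return None
        base = name[0] if name in ("x2", "y2") else name
        scale = scales.get(base)
        if scale is None:
            return v
        if scale.kind == "locus" and not isinstance(v, (tuple,)):
            chrom = row.get("chrom")
            v = (chrom, int(v)) if chrom is not None else v
        out = scale_apply(scale, v)
        if scale.kind == "band" and name in ("x2", "y2"):
            out += scale.bandwidth  # secondary channel maps to band end
        return out

    mark = view.mark
    band_y: Optional[tuple[float, float]] = None
    if "sample" in view.encoding and "sample" in scales:
        enc = view.encoding["sample"]
        v = row.get(enc.field)
        if v is None:
            return None
        try:
            top = scale_apply(scales["sample"], v)
        except Exception:
            return None  # sample filtered out of the collection order
        band_y = (top, top + scales["sample"].bandwidth)
    x = channel("x", (x0 + x1) / 2)
    y = channel("y", (y0 + y1) / 2 if band_y is None else sum(band_y) / 2)
    fill = channel("color", DEFAULT_FILL)
    opacity = channel("opacity", 1.0)
    size = channel("size", DEFAULT_POINT_SIZE)
    if x is None or y is None:
        return None
    if mark == "rect":
        rx2 = channel("x2", x)
        ry = channel("y", y0)
        ry2 = channel("y2", y1)
        if view.encoding.get("y") is None:
            # no y channel: full-height rect (track style), or the sample band
            ry, ry2 = band_y if band_y is not None else (y0, y1)
        if rx2 is None or ry is None or ry2 is None:
            return None
        xa, xb = sorted((float(x), float(rx2)))
        ya, yb = sorted((float(ry), float(ry2)))
        return Primitive("rect", xa, ya, xb, yb, fill=fill, opacity=opacity, z=z)
    if mark == "point":
        return Primitive("point", float(x), float(y), fill=fill,
                         opacity=opacity, size=float(size), z=z)
    if mark == "rule":
        rx2 = channel("x2", x)
        ry2 = channel("y2", y)
        return Primitive("rule", float(x), float(y), float(rx2), float(ry2),
                         fill=fill, opacity=opacity, z=z)
    if mark == "text":
        text = channel("text")
        if text is None:
            return None  # documented skip: text rows with missing text
        return Primitive("text", float(x), float(y), fill=fill, opacity=opacity,
                         size=float(channel("size", DEFAULT_FONT_SIZE)),
                         text=str(text), z=z)
    raise AssertionError(mark)  # pragma: no cover


# ---------------------------------------------------------------------------
# Label placement


def place_labels(candidates: Sequence[LabelCandidate],
                 min_gap: float = 2.0) -> list[LabelCandidate]:
    """Greedy priority placement: important labels first, no overlaps.

    Candidates are processed by ascending priority rank (ties by extent
    start); one is kept iff its extent padded by ``min_gap`` overlaps no
    already-kept extent.  Returns kept candidates in input order.
    """
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].priority, candidates[i].extent[0]))
    kept: list[int] = []
    for i in order:
        lo = candidates[i].extent[0] - min_gap
        hi = candidates[i].extent[1] + min_gap
        if all(hi <= candidates[j].extent[0] or lo >= candidates[j].extent[1]
               for j in kept):
            kept.append(i)
    return [candidates[i] for i in sorted(kept)]


# ---------------------------------------------------------------------------
# Export


def export_svg(scene: Scene) -> str:
    """Deterministic SVG 1.1 text for a scene (same scene → same bytes)."""
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_num(scene.width)}" height="{_num(scene.height)}" '
        f'viewBox="0 0 {_num(scene.width)} {_num(scene.height)}">\n',
    ]
    for p in sorted(scene.primitives, key=lambda q: q.z):
        common = f'fill="{p.fill}"' + (
            f' opacity="{_num(p.opacity)}"' if p.opacity != 1.0 else "")
        if p.kind == "rect":
            parts.append(
                f'  <rect x="{_num(p.x)}" y="{_num(p.y)}" '
                f'width="{_num(p.x2 - p.x)}" height="{_num(p.y2 - p.y)}" {common}/>\n')
        elif p.kind == "point":
            parts.append(
                f'  <circle cx="{_num(p.x)}" cy="{_num(p.y)}" '
                f'r="{_num(p.size / 2)}" {common}/>\n')
        elif p.kind == "rule":
            parts.append(
                f'  <line x1="{_num(p.x)}" y1="{_num(p.y)}" '
                f'x2="{_num(p.x2)}" y2="{_num(p.y2)}" '
                f'stroke="{p.fill}" stroke-width="1"/>\n')
        elif p.kind == "text":
            parts.append(
                f'  <text x="{_num(p.x)}" y="{_num(p.y)}" '
                f'font-size="{_num(p.size)}" text-anchor="middle" {common}>'
                f'{_escape(p.text or "")}</text>\n')
    parts.append("</svg>\n")
    return "".join(parts)


def export(scene: Scene, format: str, path: Union[str, Path]) -> None:
    """Write the scene as SVG or PNG."""
    path = Path(path)
    if format == "svg":
        path.write_text(export_svg(scene))
        return
    if format == "png":
        _export_png(scene, path)
        return
    raise SceneError(f"unknown export format {format!r}")


def _export_png(scene: Scene, path: Path) -> None:
    from PIL import Image, ImageDraw

    img = Image.new("RGBA", (max(1, round(scene.width)), max(1, round(scene.height))),
                    (255, 255, 255, 255))
    draw = ImageDraw.Draw(img, "RGBA")
    for p in sorted(scene.primitives, key=lambda q: q.z):
        color = _rgba(p.fill, p.opacity)
        if p.kind == "rect":
            draw.rectangle([p.x, p.y, p.x2, p.y2], fill=color)
        elif p.kind == "point":
            r = p.size / 2
            draw.ellipse([p.x - r, p.y - r, p.x + r, p.y + r], fill=color)
        elif p.kind == "rule":
            draw.line([p.x, p.y, p.x2, p.y2], fill=color, width=1)
        elif p.kind == "text":
            draw.text((p.x, p.y), p.text or "", fill=color, anchor="mm")
    img.save(path, "PNG")


def _rgba(hex_color: str, opacity: float) -> tuple[int, int, int, int]:
    h = hex_color.lstrip("#")
    return (int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16),
            round(255 * opacity))


def _num(v: float) -> str:
    return f"{v:g}"


def _escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))
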