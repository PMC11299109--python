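"""Scale resolution: mapping data values to pixel positions and colors.

Five scale kinds are supported: ``linear`` (affine, optionally clamped),
``band`` (categories to equal-width bands), ``ordinal-color`` and
``linear-color`` (categorical palette / interpolated diverging scheme), and
``locus`` — the genome-backed scale that first linearizes ``(chrom, pos)``
through the assembly and then maps the linear coordinate affinely, which is
what lets whole-genome tracks share one x axis.

``ZoomState`` models the visible window on a linear/locus axis; ``zoom_to``
is anchor-preserving multiplicative zoom clipped to the full domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping, Optional, Sequence, Union

from .genome import GenomeAssembly, Locus, linearize

__all__ = ["Scale", "ZoomState", "resolve_scale", "scale_apply", "zoom_to",
           "COLOR_SCHEMES", "CATEGORICAL_PALETTE"]

# diverging blue-white-red, for signed copy-number ratios (negative = loss)
COLOR_SCHEMES: dict[str, list[str]] = {
    "blueWhiteRed": ["#2166ac", "#ffffff", "#b2182b"],
    "whiteBlue": ["#ffffff", "#2166ac"],
    "whiteRed": ["#ffffff", "#b2182b"],
}

CATEGORICAL_PALETTE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
]


class ScaleError(ValueError):
    pass


@dataclass(frozen=True)
class Scale:
    """A resolved scale: kind + concrete domain + concrete range."""

    kind: str  # linear | band | ordinal-color | linear-color | locus
    domain: tuple
    range: tuple
    clamp: bool = False
    assembly: Optional[GenomeAssembly] = None

    @property
    def bandwidth(self) -> float:
        if self.kind != "band":
            raise ScaleError("bandwidth is only defined for band scales")
        lo, hi = self.range
        return (hi - lo) / len(self.domain)


def resolve_scale(spec: Mapping[str, Any] | None, kind: str,
                  domain: Sequence | None = None,
                  range_: Sequence | None = None,
                  assembly: GenomeAssembly | None = None) -> Scale:
    """Build a concrete :class:`Scale`, with spec values overriding inferred ones."""
    spec = spec or {}
    kind = spec.get("kind", kind)
    if kind not in ("linear", "band", "ordinal-color", "linear-color", "locus"):
        raise ScaleError(f"unknown scale kind {kind!r}")
    dom = spec.get("domain", list(domain) if domain is not None else None)
    rng = spec.get("range", list(range_) if range_ is not None else None)
    if kind == "locus":
        if assembly is None:
            raise ScaleError("locus scale requires a genome assembly")
        if dom is None:
            dom = [0, assembly.total_length]  # zoomed-out default: whole genome
    if kind in ("ordinal-color",) and rng is None:
        rng = list(CATEGORICAL_PALETTE)
    if kind == "linear-color" and rng is None:
        rng = list(COLOR_SCHEMES["blueWhiteRed"])
    if isinstance(rng, str):
        if rng not in COLOR_SCHEMES:
            raise ScaleError(f"unknown color scheme {rng!r}; "
                             f"available: {sorted(COLOR_SCHEMES)}")
        rng = list(COLOR_SCHEMES[rng])
    if dom is None or rng is None:
        raise ScaleError(f"{kind} scale could not resolve domain/range")
    if kind in ("linear", "locus", "linear-color"):
        if not (len(dom) >= 2 and dom[0] < dom[-1]):
            raise ScaleError(f"{kind} domain must have min < max, got {dom}")
    if kind in ("band", "ordinal-color"):
        if len(set(dom)) != len(dom):
            raise ScaleError("band/ordinal categories must be unique")
    return Scale(kind=kind, domain=tuple(dom), range=tuple(rng),
                 clamp=bool(spec.get("clamp", False)), assembly=assembly)


def scale_apply(scale: Scale, value: Any) -> Any:
    """Map one data value through the scale to a pixel position or color."""
    if scale.kind == "linear":
        return _affine(value, scale.domain[0], scale.domain[-1],
                       scale.range[0], scale.range[-1], scale.clamp)
    if scale.kind == "locus":
        if isinstance(value, (Locus, tuple)):
            value = linearize(scale.assembly, value)
        return _affine(value, scale.domain[0], scale.domain[-1],
                       scale.range[0], scale.range[-1], scale.clamp)
    if scale.kind == "band":
        try:
            i = scale.domain.index(value)
        except ValueError:
            raise ScaleError(f"unknown band category {value!r}") from None
        return scale.range[0] + i * scale.bandwidth
    if scale.kind == "ordinal-color":
        try:
            i = scale.domain.index(value)
        except ValueError:
            raise ScaleError(f"unknown color category {value!r}") from None
        return scale.range[i % len(scale.range)]
    if scale.kind == "linear-color":
        t = _affine(value, scale.domain[0], scale.domain[-1], 0.0, 1.0, clamp=True)
        return _interpolate_colors(scale.range, t)
    raise AssertionError(scale.kind)  # pragma: no cover


def _affine(value: float, d0: float, d1: float, r0: float, r1: float,
            clamp: bool) -> float:
    t = (float(value) - d0) / (d1 - d0)
    if clamp:
        t = min(1.0, max(0.0, t))
    return r0 + t * (r1 - r0)


def _interpolate_colors(stops: Sequence[str], t: float) -> str:
    if len(stops) == 1:
        return stops[0]
    scaled = t * (len(stops) - 1)
    i = min(int(scaled), len(stops) - 2)
    frac = scaled - i
    c0, c1 = _hex_to_rgb(stops[i]), _hex_to_rgb(stops[i + 1])
    rgb = tuple(round(a + (b - a) * frac) for a, b in zip(c0, c1))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i:i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Zooming


@dataclass(frozen=True)
class ZoomState:
    """Full domain and currently visible sub-interval on a linear axis."""

    full: tuple[float, float]
    visible: tuple[float, float]

    def __post_init__(self) -> None:
        f0, f1 = self.full
        v0, v1 = self.visible
        if not f0 < f1:
            raise ValueError("full interval must be non-empty")
        if not (f0 <= v0 < v1 <= f1):
            raise ValueError(f"visible {self.visible} must lie within full {self.full}")

    @property
    def zoom_level(self) -> float:
        return (self.full[1] - self.full[0]) / (self.visible[1] - self.visible[0])


def zoom_to(state: ZoomState, anchor: float, factor: float) -> ZoomState:
    """Zoom by ``factor`` about ``anchor``, keeping the anchor's relative
    position within the window; the result is clipped to the full domain."""
    if factor <= 0:
        raise ValueError("zoom factor must be positive")
    v0, v1 = state.visible
    width = (v1 - v0) / factor
    full_width = state.full[1] - state.full[0]
    if width >= full_width:
        return replace(state, visible=state.full)
    rel = (anchor - v0) / (v1 - v0)
    new0 = anchor - rel * width
    # clip to the full domain, preserving width
    new0 = min(max(new0, state.full[0]), state.full[1] - width)
    return replace(state, visible=(new0, new0 + width))
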